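"""Readers and writers for per-locus methylation count tables, plus the
pre-analysis filter.

Two input dialects are supported:

* a **merged TSV** with columns ``chrom``, ``pos`` (1-based), optional
  ``strand``, then one ``meth_<sample>`` / ``cov_<sample>`` column pair per
  sample named in the sample sheet;
* per-sample **bismark coverage** files (``chrom  start  end  pct
  count_methylated  count_unmethylated``, 1-based start, no header), joined
  on position with loci missing from a sample filled as coverage 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import LocusCounts

__all__ = [
    "SampleSheet",
    "MethylationTable",
    "FilterStats",
    "read_counts",
    "read_bismark",
    "write_counts",
    "filter_uninformative_loci",
]

_KEY_COLS = ("chrom", "pos", "strand")


@dataclass(frozen=True)
class SampleSheet:
    """Sample-to-condition map; ``paths`` is used by the bismark reader."""

    sample_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    paths: tuple[str | None, ...] = ()

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.conditions):
            raise ValueError("sample_ids and conditions differ in length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids must be unique")
        bad = set(self.conditions) - {"case", "control"}
        if bad:
            raise ValueError(f"conditions must be 'case' or 'control', got {bad}")
        if "case" not in self.conditions or "control" not in self.conditions:
            raise ValueError("need at least one sample per condition")
        if self.paths and len(self.paths) != len(self.sample_ids):
            raise ValueError("paths length must match sample_ids")

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"sample_id", "condition"}
        if not required.issubset(df.columns):
            raise ValueError(f"sample sheet needs columns {sorted(required)}")
        paths = (
            tuple(df["path"]) if "path" in df.columns else tuple([None] * len(df))
        )
        return cls(
            sample_ids=tuple(df["sample_id"]),
            conditions=tuple(df["condition"]),
            paths=paths,
        )

    def ids_for(self, condition: str) -> list[str]:
        return [s for s, c in zip(self.sample_ids, self.conditions) if c == condition]


@dataclass
class MethylationTable:
    """Validated locus-by-sample count table.

    ``frame`` holds the key columns plus ``meth_<sid>`` / ``cov_<sid>`` for
    every sample in ``sheet``; extra columns (e.g. a simulation truth label)
    are carried through untouched.
    """

    frame: pd.DataFrame
    sheet: SampleSheet

    @property
    def n_loci(self) -> int:
        return len(self.frame)

    def _cols(self, condition: str, what: str) -> list[str]:
        return [f"{what}_{sid}" for sid in self.sheet.ids_for(condition)]

    def counts_matrix(self, condition: str, what: str) -> np.ndarray:
        return self.frame[self._cols(condition, what)].to_numpy(dtype=np.int64)

    def to_locus_counts(self) -> list[LocusCounts]:
        cov1 = self.counts_matrix("case", "cov")
        m1 = self.counts_matrix("case", "meth")
        cov2 = self.counts_matrix("control", "cov")
        m2 = self.counts_matrix("control", "meth")
        return [
            LocusCounts(cov1[i], m1[i], cov2[i], m2[i])
            for i in range(self.n_loci)
        ]

    def pooled_difference(self) -> np.ndarray:
        """Pooled ``p_hat_case - p_hat_control`` per locus (NaN when a
        condition has zero pooled coverage)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            p1 = self.counts_matrix("case", "meth").sum(axis=1) / self.counts_matrix(
                "case", "cov"
            ).sum(axis=1)
            p2 = self.counts_matrix("control", "meth").sum(
                axis=1
            ) / self.counts_matrix("control", "cov").sum(axis=1)
        return p1 - p2


def _validate_counts(df: pd.DataFrame, sheet: SampleSheet, source: str) -> None:
    keys = [c for c in _KEY_COLS if c in df.columns]
    dup = df.duplicated(subset=keys)
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(f"{source}: duplicate locus at data row {row + 1}")
    for sid in sheet.sample_ids:
        for col in (f"meth_{sid}", f"cov_{sid}"):
            if col not in df.columns:
                raise ValueError(f"{source}: missing column {col!r}")
        meth = df[f"meth_{sid}"].to_numpy()
        cov = df[f"cov_{sid}"].to_numpy()
        bad = (meth > cov) | (meth < 0) | (cov < 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{source}: methylated count exceeds coverage (or negative) "
                f"for sample {sid!r} at data row {row + 1}"
            )


def read_counts(path, sheet: SampleSheet) -> MethylationTable:
    """Read a merged per-locus count TSV and validate it."""
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ValueError(f"{path}: failed to parse merged count table: {exc}") from exc
    if "chrom" not in df.columns or "pos" not in df.columns:
        raise ValueError(f"{path}: merged table needs 'chrom' and 'pos' columns")
    for sid in sheet.sample_ids:
        for col in (f"meth_{sid}", f"cov_{sid}"):
            if col in df.columns and not np.issubdtype(df[col].dtype, np.number):
                bad = pd.to_numeric(df[col], errors="coerce").isna()
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(f"{path}: malformed count at data row {row + 1}")
    _validate_counts(df, sheet, str(path))
    return MethylationTable(frame=df.reset_index(drop=True), sheet=sheet)


def read_bismark(
    sheet: SampleSheet, strict_intersection: bool = False
) -> MethylationTable:
    """Join per-sample bismark-coverage files on genomic position.

    Loci absent from a sample get coverage 0 there; ``strict_intersection``
    instead keeps only loci observed in every sample.
    """
    if not sheet.paths or any(p is None for p in sheet.paths):
        raise ValueError("bismark input requires a path for every sample")
    merged: pd.DataFrame | None = None
    for sid, path in zip(sheet.sample_ids, sheet.paths):
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=["chrom", "start", "end", "pct", "n_meth", "n_unmeth"],
        )
        if df.isna().any().any():
            row = int(np.flatnonzero(df.isna().any(axis=1).to_numpy())[0])
            raise ValueError(f"{path}: malformed row at data row {row + 1}")
        part = pd.DataFrame(
            {
                "chrom": df["chrom"].astype(str),
                "pos": df["start"].astype(np.int64),
                f"meth_{sid}": df["n_meth"].astype(np.int64),
                f"cov_{sid}": (df["n_meth"] + df["n_unmeth"]).astype(np.int64),
            }
        )
        how = "inner" if strict_intersection else "outer"
        merged = part if merged is None else merged.merge(
            part, on=["chrom", "pos"], how=how
        )
    merged = merged.fillna(0)
    for sid in sheet.sample_ids:
        merged[f"meth_{sid}"] = merged[f"meth_{sid}"].astype(np.int64)
        merged[f"cov_{sid}"] = merged[f"cov_{sid}"].astype(np.int64)
    merged = merged.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    _validate_counts(merged, sheet, "bismark input")
    return MethylationTable(frame=merged, sheet=sheet)


def write_counts(table: MethylationTable, path) -> None:
    """Write the merged TSV dialect with a stable column order."""
    keys = [c for c in _KEY_COLS if c in table.frame.columns]
    count_cols = []
    for sid in table.sheet.sample_ids:
        count_cols += [f"meth_{sid}", f"cov_{sid}"]
    extra = [
        c for c in table.frame.columns if c not in keys and c not in count_cols
    ]
    table.frame[keys + count_cols + extra].to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FilterStats:
    """Removed-locus counts per filter category."""

    fully_methylated: int
    unmethylated: int
    zero_coverage: int

    @property
    def total(self) -> int:
        return self.fully_methylated + self.unmethylated + self.zero_coverage


def filter_uninformative_loci(
    table: MethylationTable,
) -> tuple[MethylationTable, FilterStats]:
    """Drop loci carrying no differential-methylation information.

    Removes loci where every covered sample is fully methylated (M = C) or
    every covered sample is unmethylated (M = 0) — no difference can exist
    there — and loci with zero pooled coverage in either condition (counted
    separately).
    """
    if table.n_loci == 0:
        return table, FilterStats(0, 0, 0)
    cov = np.column_stack(
        [table.counts_matrix("case", "cov"), table.counts_matrix("control", "cov")]
    )
    meth = np.column_stack(
        [table.counts_matrix("case", "meth"), table.counts_matrix("control", "meth")]
    )
    pooled_case = table.counts_matrix("case", "cov").sum(axis=1)
    pooled_control = table.counts_matrix("control", "cov").sum(axis=1)
    zero_cov = (pooled_case == 0) | (pooled_control == 0)
    observed = cov > 0
    fully = (~zero_cov) & np.all((meth == cov) | ~observed, axis=1)
    none = (~zero_cov) & np.all((meth == 0) | ~observed, axis=1)
    keep = ~(zero_cov | fully | none)
    stats = FilterStats(
        fully_methylated=int(fully.sum()),
        unmethylated=int(none.sum()),
        zero_coverage=int(zero_cov.sum()),
    )
    filtered = MethylationTable(
        frame=table.frame.loc[keep].reset_index(drop=True), sheet=table.sheet
    )
    return filtered, stats
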