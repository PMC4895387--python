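"""Core containers for two-condition methylation count data.

Counts follow the usual bisulfite-sequencing convention: at each CpG locus a
replicate contributes ``C`` aligned reads (coverage) of which ``M`` report a
methylated cytosine; ``N = C - M`` reads are unmethylated.  Condition 1 is the
"case" (e.g. tumour) and condition 2 the "control".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LocusCounts", "Hyperparameters", "BetaParams"]


def _as_count_vector(x, name: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x))
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D vector")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.round(arr)
        if not np.allclose(arr, rounded, atol=1e-9):
            raise ValueError(f"{name} must contain integers")
        arr = rounded
    arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise ValueError(f"{name} must be non-negative")
    return arr


@dataclass(frozen=True)
class LocusCounts:
    """Read counts at one CpG locus for all replicates of both conditions.

    Parameters
    ----------
    coverage_case, meth_case
        Coverage and methylated-read counts for the case replicates.
    coverage_control, meth_control
        The same for the control replicates.
    """

    coverage_case: np.ndarray
    meth_case: np.ndarray
    coverage_control: np.ndarray
    meth_control: np.ndarray

    def __post_init__(self) -> None:
        cc = _as_count_vector(self.coverage_case, "coverage_case")
        mc = _as_count_vector(self.meth_case, "meth_case")
        ck = _as_count_vector(self.coverage_control, "coverage_control")
        mk = _as_count_vector(self.meth_control, "meth_control")
        if cc.shape != mc.shape:
            raise ValueError("case coverage and methylated counts differ in length")
        if ck.shape != mk.shape:
            raise ValueError("control coverage and methylated counts differ in length")
        if (mc > cc).any() or (mk > ck).any():
            raise ValueError("methylated reads exceed coverage")
        object.__setattr__(self, "coverage_case", cc)
        object.__setattr__(self, "meth_case", mc)
        object.__setattr__(self, "coverage_control", ck)
        object.__setattr__(self, "meth_control", mk)

    @property
    def n_case(self) -> int:
        return self.coverage_case.size

    @property
    def n_control(self) -> int:
        return self.coverage_control.size

    # pooled sufficient statistics (methylated / unmethylated read totals)
    @property
    def meth_case_total(self) -> int:
        return int(self.meth_case.sum())

    @property
    def unmeth_case_total(self) -> int:
        return int((self.coverage_case - self.meth_case).sum())

    @property
    def meth_control_total(self) -> int:
        return int(self.meth_control.sum())

    @property
    def unmeth_control_total(self) -> int:
        return int((self.coverage_control - self.meth_control).sum())

    def swapped(self) -> "LocusCounts":
        """Return the locus with the case and control blocks exchanged."""
        return LocusCounts(
            coverage_case=self.coverage_control,
            meth_case=self.meth_control,
            coverage_control=self.coverage_case,
            meth_control=self.meth_case,
        )


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters.

    ``(alpha1, beta1)``, ``(alpha2, beta2)`` and ``(alpha3, beta3)`` are the
    Beta prior shapes for the methylation proportion(s) of equal-, hypo- and
    hyper-methylated loci respectively; ``(k0, k1, k2)`` are the Dirichlet
    shapes of the prior on the three group probabilities.  The non-informative
    default sets all nine to one.
    """

    alpha1: float = 1.0
    beta1: float = 1.0
    alpha2: float = 1.0
    beta2: float = 1.0
    alpha3: float = 1.0
    beta3: float = 1.0
    k0: float = 1.0
    k1: float = 1.0
    k2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "beta1", "alpha2", "beta2", "alpha3", "beta3",
                     "k0", "k1", "k2"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"hyperparameter {name} must be strictly positive")
            object.__setattr__(self, name, v)

    @property
    def dirichlet(self) -> np.ndarray:
        return np.array([self.k0, self.k1, self.k2], dtype=float)


@dataclass(frozen=True)
class BetaParams:
    """Shape pair of a Beta distribution."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)) or self.a <= 0 or self.b <= 0:
            raise ValueError("Beta shapes must be strictly positive and finite")
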