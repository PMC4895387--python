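"""Synthetic bisulfite-sequencing data with known three-group truth, and the
evaluation metrics used to score callers against that truth.

The generator mirrors a case-control RRBS benchmark design: each locus is
assigned to the equal- (0), hypo- (1) or hyper-methylated (2) group, true
methylation proportions are drawn from per-group pools, coverage is drawn per
replicate, and methylated read counts are Binomial(C, p).  An optional
"subject effect" perturbs the proportion independently per replicate around
the locus value, emulating biological variation within a condition.

Proportion pools come in two flavours:

* **empirical** — a user-supplied table of per-locus proportion estimates
  from a real dataset, partitioned by the effect-size rule below; this
  replicates a resampling-from-real-data design exactly.
* **parametric** — Beta (or Beta-mixture) pools; the packaged default, so no
  external data are needed.  The default equal-group pool is a bimodal Beta
  mixture concentrated near 0 and 1, the usual shape of RRBS methylation
  levels.

The effect-size rule: given per-locus pooled estimates and their difference
``d_hat = p_hat_case - p_hat_control``, loci with ``|d_hat| < 0.005`` are
labelled equal, ``d_hat > gamma`` hyper and ``d_hat < -gamma`` hypo; the
remaining band is excluded so that the tuning parameter ``gamma`` controls
both effect size and group abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import compute_log_marginals
from .sampler import ChainConfig, run_chain
from .types import Hyperparameters, LocusCounts

__all__ = [
    "SimulationDesign",
    "TrueProportions",
    "EvaluationResult",
    "GROUP_FRACTION_PRESETS",
    "partition_by_gamma",
    "assign_truth_labels",
    "draw_true_proportions",
    "simulate_counts",
    "simulate_dataset",
    "pools_from_estimates",
    "evaluate_calls",
    "run_benchmark",
    "BenchmarkResult",
]

EXCLUDED = -1  # label for loci in the (0.005, gamma] effect-size band
_EQUAL_BAND = 0.005

# Observed group abundances at the two printed anchor values of gamma:
# (equal, hypo, hyper) fractions.
GROUP_FRACTION_PRESETS: dict[float, tuple[float, float, float]] = {
    0.01: (1.0 - 0.4328 - 0.2944, 0.4328, 0.2944),
    0.2: (1.0 - 0.059 - 0.046, 0.059, 0.046),
}


def _default_pools() -> dict:
    return {
        # bimodal mixture near 0 and 1 with a small mid-range component
        0: {
            "kind": "beta_mixture",
            "components": [(0.4, 0.08, 5.0), (0.4, 0.92, 5.0), (0.2, 0.5, 2.0)],
        },
        1: {"kind": "beta_pair", "mean_case": 0.2, "mean_control": 0.6, "size": 20.0},
        2: {"kind": "beta_pair", "mean_case": 0.6, "mean_control": 0.2, "size": 20.0},
    }


@dataclass
class SimulationDesign:
    """Generator controls.

    Defaults follow the benchmark conditions: 20,000 loci, two replicates
    per condition, coverage 1 + Poisson(20), and group fractions at the
    ``gamma = 0.2`` anchor (5.9 % hypo, 4.6 % hyper).
    """

    n_loci: int = 20000
    n_case: int = 2
    n_control: int = 2
    gamma: float = 0.2
    group_fractions: tuple[float, float, float] | None = None
    coverage_model: dict = field(
        default_factory=lambda: {"kind": "shifted_poisson", "mean": 20.0}
    )
    proportion_pools: dict | None = None
    subject_effect: bool = False
    subject_concentration: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1 or self.n_case < 1 or self.n_control < 1:
            raise ValueError("n_loci, n_case and n_control must be positive")
        if self.gamma <= _EQUAL_BAND:
            raise ValueError(f"gamma must exceed {_EQUAL_BAND}")
        if self.group_fractions is None:
            preset = GROUP_FRACTION_PRESETS.get(round(self.gamma, 6))
            self.group_fractions = preset if preset else GROUP_FRACTION_PRESETS[0.2]
        fr = np.asarray(self.group_fractions, dtype=float)
        if fr.shape != (3,) or (fr < 0).any() or (fr > 1).any():
            raise ValueError("group_fractions must be three values in [0, 1]")
        if abs(fr.sum() - 1.0) > 1e-12:
            raise ValueError("group_fractions must sum to 1")
        self.group_fractions = tuple(fr)
        if self.proportion_pools is None:
            self.proportion_pools = _default_pools()
        if self.subject_concentration <= 0:
            raise ValueError("subject_concentration must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationDesign":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown design keys: {sorted(unknown)}")
        d = dict(d)
        if "group_fractions" in d and d["group_fractions"] is not None:
            d["group_fractions"] = tuple(d["group_fractions"])
        if "proportion_pools" in d and d["proportion_pools"] is not None:
            d["proportion_pools"] = {
                int(k): v for k, v in d["proportion_pools"].items()
            }
        return cls(**d)


@dataclass
class TrueProportions:
    """Per-locus true proportions; per-replicate matrices when the subject
    effect is on (otherwise they broadcast the locus values)."""

    p_case: np.ndarray
    p_control: np.ndarray
    p_case_rep: np.ndarray | None = None
    p_control_rep: np.ndarray | None = None


def partition_by_gamma(d_hat, gamma: float) -> np.ndarray:
    """Label loci by observed proportion difference.

    ``|d| < 0.005`` -> 0 (equal); ``d > gamma`` -> 2 (hyper);
    ``d < -gamma`` -> 1 (hypo); the in-between band (inclusive of the
    boundaries) -> ``EXCLUDED`` (-1).
    """
    if gamma <= _EQUAL_BAND:
        raise ValueError(
            f"gamma must exceed {_EQUAL_BAND}; the rule is contradictory otherwise"
        )
    d = np.asarray(d_hat, dtype=float)
    labels = np.full(d.shape, EXCLUDED, dtype=np.int64)
    labels[np.abs(d) < _EQUAL_BAND] = 0
    labels[d > gamma] = 2
    labels[d < -gamma] = 1
    return labels


def pools_from_estimates(
    p_case, p_control, gamma: float, pooled: np.ndarray | None = None
) -> dict:
    """Build empirical proportion pools from per-locus estimates.

    The equal-group pool holds the pooled common-proportion estimate of each
    equal-labelled locus (``pooled`` defaults to the mean of the two
    condition estimates); the hypo/hyper pools hold the (case, control)
    estimate pairs of loci passing the gamma rule.
    """
    p1 = np.asarray(p_case, dtype=float)
    p2 = np.asarray(p_control, dtype=float)
    labels = partition_by_gamma(p1 - p2, gamma)
    if pooled is None:
        pooled = (p1 + p2) / 2.0
    pools = {}
    for g in (0, 1, 2):
        mask = labels == g
        if g == 0:
            pools[0] = {"kind": "empirical", "values": pooled[mask]}
        else:
            pools[g] = {
                "kind": "empirical_pair",
                "values": np.column_stack([p1[mask], p2[mask]]),
            }
    return pools


def assign_truth_labels(design: SimulationDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw locus group labels i.i.d. from the design's group fractions."""
    return rng.choice(3, size=design.n_loci, p=np.asarray(design.group_fractions))


def _beta_shapes(mean: float, size: float) -> tuple[float, float]:
    return mean * size, (1.0 - mean) * size


def _draw_scalar_pool(pool: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = pool["kind"]
    if kind == "beta":
        a, b = _beta_shapes(pool["mean"], pool["size"])
        return rng.beta(a, b, size=n)
    if kind == "beta_mixture":
        comps = pool["components"]
        weights = np.array([c[0] for c in comps], dtype=float)
        weights = weights / weights.sum()
        which = rng.choice(len(comps), size=n, p=weights)
        out = np.empty(n)
        for ci, (_, mean, size) in enumerate(comps):
            mask = which == ci
            a, b = _beta_shapes(mean, size)
            out[mask] = rng.beta(a, b, size=int(mask.sum()))
        return out
    if kind == "empirical":
        values = np.asarray(pool["values"], dtype=float)
        if values.size == 0:
            raise ValueError("empirical pool for a required group is empty")
        return values[rng.integers(values.size, size=n)]
    raise ValueError(f"unknown scalar pool kind {kind!r}")


def _draw_pair_pool(
    pool: dict, n: int, order: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    kind = pool["kind"]
    if kind == "beta_pair":
        a1, b1 = _beta_shapes(pool["mean_case"], pool["size"])
        a2, b2 = _beta_shapes(pool["mean_control"], pool["size"])
        p1 = rng.beta(a1, b1, size=n)
        p2 = rng.beta(a2, b2, size=n)
        bad = (p1 >= p2) if order == "lt" else (p1 <= p2)
        tries = 0
        while bad.any():
            nb = int(bad.sum())
            p1[bad] = rng.beta(a1, b1, size=nb)
            p2[bad] = rng.beta(a2, b2, size=nb)
            bad = (p1 >= p2) if order == "lt" else (p1 <= p2)
            tries += 1
            if tries > 10000:
                raise RuntimeError("order-constrained resampling did not terminate")
        return p1, p2
    if kind == "empirical_pair":
        values = np.asarray(pool["values"], dtype=float)
        if values.size == 0:
            raise ValueError("empirical pool for a required group is empty")
        rows = values[rng.integers(values.shape[0], size=n)]
        return rows[:, 0], rows[:, 1]
    raise ValueError(f"unknown pair pool kind {kind!r}")


def draw_true_proportions(
    design: SimulationDesign, labels: np.ndarray, rng: np.random.Generator
) -> TrueProportions:
    """Draw (p_case, p_control) per locus from the group pools.

    Equal-group loci get a single shared proportion; hypo/hyper pairs honour
    their order constraint (parametric pools resample violations).  With the
    subject effect on, per-replicate proportions are drawn from a Beta with
    mean equal to the locus proportion and concentration
    ``subject_concentration``.
    """
    labels = np.asarray(labels)
    n = labels.size
    p_case = np.empty(n)
    p_control = np.empty(n)
    pools = design.proportion_pools
    mask0 = labels == 0
    if mask0.any():
        shared = _draw_scalar_pool(pools[0], int(mask0.sum()), rng)
        p_case[mask0] = shared
        p_control[mask0] = shared
    for g, order in ((1, "lt"), (2, "gt")):
        mask = labels == g
        if mask.any():
            p1, p2 = _draw_pair_pool(pools[g], int(mask.sum()), order, rng)
            p_case[mask] = p1
            p_control[mask] = p2
    props = TrueProportions(p_case=p_case, p_control=p_control)
    if design.subject_effect:
        s = design.subject_concentration
        props.p_case_rep = _perturb(p_case, design.n_case, s, rng)
        props.p_control_rep = _perturb(p_control, design.n_control, s, rng)
    return props


def _perturb(p: np.ndarray, n_rep: int, s: float, rng: np.random.Generator) -> np.ndarray:
    out = np.empty((p.size, n_rep))
    # degenerate proportions (0 or 1) have no Beta representation; keep exact
    interior = (p > 0.0) & (p < 1.0)
    for j in range(n_rep):
        col = np.array(p, copy=True)
        pi = p[interior]
        col[interior] = rng.beta(pi * s, (1.0 - pi) * s)
        out[:, j] = col
    return out


def _draw_coverage(
    model: dict, shape: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    kind = model["kind"]
    if kind == "shifted_poisson":
        return 1 + rng.poisson(float(model["mean"]), size=shape)
    if kind == "empirical":
        values = np.asarray(model["values"], dtype=np.int64)
        if values.size == 0:
            raise ValueError("empirical coverage table is empty")
        return np.maximum(values[rng.integers(values.size, size=shape)], 1)
    if kind == "constant":
        return np.full(shape, max(int(model["value"]), 1), dtype=np.int64)
    raise ValueError(f"unknown coverage model {kind!r}")


def simulate_counts(
    props: TrueProportions, design: SimulationDesign, rng: np.random.Generator
) -> list[LocusCounts]:
    """Draw coverages and Binomial methylated counts for every locus."""
    n = props.p_case.size
    cov1 = _draw_coverage(design.coverage_model, (n, design.n_case), rng)
    cov2 = _draw_coverage(design.coverage_model, (n, design.n_control), rng)
    p1 = (
        props.p_case_rep
        if props.p_case_rep is not None
        else np.repeat(props.p_case[:, None], design.n_case, axis=1)
    )
    p2 = (
        props.p_control_rep
        if props.p_control_rep is not None
        else np.repeat(props.p_control[:, None], design.n_control, axis=1)
    )
    m1 = rng.binomial(cov1, p1)
    m2 = rng.binomial(cov2, p2)
    return [
        LocusCounts(cov1[i], m1[i], cov2[i], m2[i]) for i in range(n)
    ]


@dataclass
class SimulatedDataset:
    data: list[LocusCounts]
    truth: np.ndarray
    proportions: TrueProportions


def simulate_dataset(
    design: SimulationDesign, seed: int | None = None
) -> SimulatedDataset:
    """Labels -> proportions -> counts, fully seeded and reproducible."""
    rng = np.random.default_rng(design.seed if seed is None else seed)
    labels = assign_truth_labels(design, rng)
    props = draw_true_proportions(design, labels, rng)
    data = simulate_counts(props, design, rng)
    return SimulatedDataset(data=data, truth=labels, proportions=props)


@dataclass
class EvaluationResult:
    """The five benchmark metrics plus the truth-by-call confusion table.

    Rates with a zero denominator are NaN ("undefined"), never 0.
    """

    fdr: float
    mdfdr: float
    tpr: float
    tpr_hypo: float
    tpr_hyper: float
    confusion: np.ndarray

    def as_dict(self) -> dict:
        return {
            "fdr": self.fdr,
            "mdfdr": self.mdfdr,
            "tpr": self.tpr,
            "tpr_hypo": self.tpr_hypo,
            "tpr_hyper": self.tpr_hyper,
        }


def evaluate_calls(truth, calls, directional: bool = True) -> EvaluationResult:
    """Score three-way calls against three-way truth.

    * FDR: fraction of discoveries (call != 0) whose truth is 0.
    * mdFDR: as FDR, plus wrong-direction discoveries (truth 1 called 2 or
      vice versa) counted as false.
    * TPR: fraction of true DML (truth != 0) discovered, direction ignored.
    * TPR_hypo / TPR_hyper: fraction of truly hypo/hyper loci called with
      the matching label (``directional=False`` counts any discovery).
    """
    truth = np.asarray(truth, dtype=np.int64)
    calls = np.asarray(calls, dtype=np.int64)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls must have equal length")
    for name, v in (("truth", truth), ("calls", calls)):
        if v.size and (v.min() < 0 or v.max() > 2):
            raise ValueError(f"{name} labels must be in {{0, 1, 2}}")
    disc = calls != 0
    n_disc = int(disc.sum())
    nan = float("nan")
    if n_disc:
        n_null = int((truth[disc] == 0).sum())
        n_wrong_dir = int(
            (disc & (((truth == 1) & (calls == 2)) | ((truth == 2) & (calls == 1)))).sum()
        )
        fdr = n_null / n_disc
        mdfdr = (n_null + n_wrong_dir) / n_disc
    else:
        fdr = mdfdr = nan
    n_dml = int((truth != 0).sum())
    tpr = float(((truth != 0) & disc).sum()) / n_dml if n_dml else nan
    tprs = {}
    for g, name in ((1, "tpr_hypo"), (2, "tpr_hyper")):
        denom = int((truth == g).sum())
        if denom:
            hit = (truth == g) & ((calls == g) if directional else disc)
            tprs[name] = float(hit.sum()) / denom
        else:
            tprs[name] = nan
    confusion = np.zeros((3, 3), dtype=np.int64)
    np.add.at(confusion, (truth, calls), 1)
    return EvaluationResult(
        fdr=fdr, mdfdr=mdfdr, tpr=tpr, confusion=confusion, **tprs
    )


@dataclass
class BenchmarkResult:
    summary: pd.DataFrame
    per_replicate: dict[str, list[EvaluationResult]]
    matched_fdr_threshold: float


def run_benchmark(
    design: SimulationDesign,
    n_reps: int = 10,
    methods: tuple[str, ...] = ("bayes", "ztest", "logistic"),
    fdr_matching: bool = True,
    nominal_fdr: float = 0.05,
    chain_config: ChainConfig | None = None,
    hyper: Hyperparameters | None = None,
    base_seed: int | None = None,
) -> BenchmarkResult:
    """Average the five metrics per method over replicate datasets.

    With ``fdr_matching`` on (and ``bayes`` among the methods), the realized
    FDR of the Bayesian caller, averaged over replicates, becomes the
    q-value threshold for the frequentist baselines — the matched-FDR
    comparison protocol.  Fully deterministic given the seeds.
    """
    from .baselines import run_baseline  # local import to avoid cycles

    known = {"bayes", "ztest", "logistic"}
    unknown = set(methods) - known
    if unknown:
        raise ValueError(f"unknown benchmark methods: {sorted(unknown)}")
    hyper = hyper or Hyperparameters()
    base = ChainConfig() if chain_config is None else chain_config
    ss = np.random.SeedSequence(design.seed if base_seed is None else base_seed)
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]

    datasets = [simulate_dataset(design, seed=s) for s in rep_seeds]
    per_rep: dict[str, list[EvaluationResult]] = {m: [] for m in methods}

    threshold = nominal_fdr
    if "bayes" in methods:
        for ds, s in zip(datasets, rep_seeds):
            cfg = replace_config(base, seed=s)
            summary = run_chain(ds.data, hyper, cfg)
            per_rep["bayes"].append(evaluate_calls(ds.truth, summary.call))
        if fdr_matching:
            fdrs = [r.fdr for r in per_rep["bayes"] if np.isfinite(r.fdr)]
            if fdrs:
                threshold = float(np.mean(fdrs))

    for method in methods:
        if method == "bayes":
            continue
        for ds in datasets:
            _, _, calls = run_baseline(ds.data, method=method, fdr_level=threshold)
            per_rep[method].append(evaluate_calls(ds.truth, calls))

    rows = {}
    for method in methods:
        metrics = pd.DataFrame([r.as_dict() for r in per_rep[method]])
        rows[method] = metrics.mean(skipna=True)
    summary = pd.DataFrame(rows).T
    summary.index.name = "method"
    return BenchmarkResult(
        summary=summary, per_replicate=per_rep, matched_fdr_threshold=threshold
    )


def replace_config(config: ChainConfig, **kwargs) -> ChainConfig:
    """Copy a chain config with some fields replaced."""
    return replace(config, **kwargs)
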