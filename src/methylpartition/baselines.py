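"""Comparator methods: pooled two-proportion z-test, per-locus binomial
logistic regression, q-value multiple-testing control, and the sign-based
direction call.

Both frequentist tests produce one p-value per locus and are thresholded
after q-value adjustment; the hypo/hyper direction of a discovery is then
decided post hoc from the sign of the pooled methylation-proportion
difference ``d_hat = p_hat_case - p_hat_control`` — the ad-hoc two-step
practice the one-step partition model is benchmarked against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .types import LocusCounts

__all__ = [
    "LocusTestResult",
    "z_test_pooled",
    "logistic_regression_test",
    "qvalue_adjust",
    "call_direction",
    "run_baseline",
]


@dataclass(frozen=True)
class LocusTestResult:
    """Per-locus frequentist test outcome.

    ``estimated_difference`` is the pooled proportion difference
    ``d_hat = sum(M_case)/sum(C_case) - sum(M_control)/sum(C_control)``;
    ``direction`` is 1 (hypo) when it is negative, 2 (hyper) when positive,
    0 otherwise.  ``degenerate`` flags loci where the test statistic is
    undefined (the p-value is then 1).
    """

    statistic: float
    p_value: float
    estimated_difference: float
    direction: int
    degenerate: bool = False
    method: str = ""


def _pooled_difference(locus: LocusCounts) -> tuple[float, float, float]:
    c1 = locus.coverage_case.sum()
    c2 = locus.coverage_control.sum()
    if c1 == 0 or c2 == 0:
        raise ValueError("pooled coverage must be positive in both conditions")
    p1 = locus.meth_case_total / c1
    p2 = locus.meth_control_total / c2
    return p1, p2, p1 - p2


def _sign_direction(d_hat: float) -> int:
    if d_hat < 0:
        return 1
    if d_hat > 0:
        return 2
    return 0


def z_test_pooled(locus: LocusCounts) -> LocusTestResult:
    """Two-proportion z-test on read counts pooled within each condition.

    ``z = (p1 - p2) / sqrt(p(1-p)(1/C1 + 1/C2))`` with the pooled proportion
    ``p``; two-sided normal p-value.  A pooled proportion of exactly 0 or 1
    makes the standard error zero; such loci are flagged degenerate with
    p-value 1.
    """
    p1, p2, d_hat = _pooled_difference(locus)
    c1 = int(locus.coverage_case.sum())
    c2 = int(locus.coverage_control.sum())
    pooled = (locus.meth_case_total + locus.meth_control_total) / (c1 + c2)
    if pooled == 0.0 or pooled == 1.0:
        return LocusTestResult(0.0, 1.0, d_hat, _sign_direction(d_hat),
                               degenerate=True, method="ztest")
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / c1 + 1.0 / c2))
    z = (p1 - p2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return LocusTestResult(float(z), float(min(p, 1.0)), d_hat,
                           _sign_direction(d_hat), method="ztest")


def _fit_binomial_glm(successes, failures, cond):
    endog = np.column_stack([successes, failures]).astype(float)
    exog = np.column_stack([np.ones_like(cond, dtype=float), cond.astype(float)])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(maxiter=200)


def logistic_regression_test(
    locus: LocusCounts,
    min_coverage: int = 0,
    use_lrt: bool = False,
) -> LocusTestResult:
    """Per-locus binomial GLM ``logit(p) = b0 + b1 * condition``.

    Each replicate contributes a (methylated, unmethylated) success/failure
    row; the reported p-value is the Wald test on the condition effect
    ``b1``.  Perfect separation (the Wald statistic degenerates) falls back
    to a likelihood-ratio test against the intercept-only model, as does
    ``use_lrt=True``.  ``min_coverage`` optionally drops replicates below a
    per-sample read threshold before fitting.
    """
    p1, p2, d_hat = _pooled_difference(locus)
    cov = np.concatenate([locus.coverage_case, locus.coverage_control])
    meth = np.concatenate([locus.meth_case, locus.meth_control])
    cond = np.concatenate(
        [np.ones(locus.n_case), np.zeros(locus.n_control)]
    )
    keep = cov > max(0, min_coverage - 1)
    cov, meth, cond = cov[keep], meth[keep], cond[keep]
    direction = _sign_direction(d_hat)
    if cov.size == 0 or len(np.unique(cond)) < 2:
        return LocusTestResult(0.0, 1.0, d_hat, direction,
                               degenerate=True, method="logistic")
    try:
        res = _fit_binomial_glm(meth, cov - meth, cond)
    except Exception:
        return LocusTestResult(0.0, 1.0, d_hat, direction,
                               degenerate=True, method="logistic")
    bse = float(res.bse[1])
    beta = float(res.params[1])
    wald_ok = (
        res.converged and np.isfinite(bse) and bse < 1e3 and abs(beta) < 15.0
    )
    if wald_ok and not use_lrt:
        z = beta / bse
        return LocusTestResult(float(z), float(res.pvalues[1]), d_hat,
                               direction, method="logistic")
    # likelihood-ratio fallback (and explicit LRT mode)
    try:
        res0 = _fit_binomial_glm(
            meth, cov - meth, np.zeros_like(cond)
        )
        lrt = max(float(res0.deviance - res.deviance), 0.0)
    except Exception:
        return LocusTestResult(0.0, 1.0, d_hat, direction,
                               degenerate=True, method="logistic")
    p = float(stats.chi2.sf(lrt, df=1))
    stat = float(np.sign(d_hat) * np.sqrt(lrt))
    return LocusTestResult(stat, p, d_hat, direction,
                           degenerate=not (wald_ok or use_lrt),
                           method="logistic")


def qvalue_adjust(
    p_values, pi0: float | None = None, lambda_: float = 0.5
) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    ``pi0_hat = min{1, #{p > lambda} / ((1 - lambda) m)}``; q-values are the
    monotonized ``pi0 * m * p_(i) / i``.  Forcing ``pi0=1`` reproduces
    Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = min(1.0, float((p > lambda_).sum()) / ((1.0 - lambda_) * m))
        pi0 = max(pi0, 1.0 / m)  # guard against a zero estimate
    if not (0.0 < pi0 <= 1.0):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def call_direction(result: LocusTestResult, discovery: bool) -> int:
    """Three-way label from a binary discovery plus the sign of ``d_hat``.

    0 when not a discovery or when the estimated difference is exactly zero
    (a discovery that cannot be oriented); else 1 for negative and 2 for
    positive differences.
    """
    if not discovery:
        return 0
    if result.estimated_difference < 0:
        return 1
    if result.estimated_difference > 0:
        return 2
    return 0


def run_baseline(
    data: list[LocusCounts],
    method: str = "ztest",
    fdr_level: float = 0.05,
    pi0: float | None = None,
    p_values: np.ndarray | None = None,
    min_coverage: int = 0,
):
    """Test every locus, adjust, threshold, and orient.

    ``method`` is ``'ztest'``, ``'logistic'`` or ``'external'`` (the latter
    takes precomputed ``p_values`` and orients by the pooled difference).
    Returns ``(results, q_values, calls)``.
    """
    if method == "ztest":
        results = [z_test_pooled(locus) for locus in data]
    elif method == "logistic":
        results = [
            logistic_regression_test(locus, min_coverage=min_coverage)
            for locus in data
        ]
    elif method == "external":
        if p_values is None:
            raise ValueError("method='external' requires p_values")
        results = []
        for locus, p in zip(data, np.asarray(p_values, dtype=float)):
            _, _, d_hat = _pooled_difference(locus)
            results.append(
                LocusTestResult(np.nan, float(p), d_hat,
                                _sign_direction(d_hat), method="external")
            )
    else:
        raise ValueError(f"unknown baseline method {method!r}")
    q = qvalue_adjust(np.array([r.p_value for r in results]), pi0=pi0)
    calls = np.array(
        [call_direction(r, qi <= fdr_level) for r, qi in zip(results, q)],
        dtype=np.int64,
    )
    return results, q, calls
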