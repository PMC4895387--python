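"""Collapsed marginal likelihoods and the partition posterior.

The model partitions CpG loci into three groups according to how the true
methylation proportions compare between a case and a control condition:

* group 0 (equal): ``p_case = p_control``, a single shared proportion with a
  Beta(alpha1, beta1) prior;
* group 1 (hypo): ``p_case < p_control``, with a truncated product-Beta prior
  ``2 f(p_case) f(p_control) 1{p_case < p_control}``;
* group 2 (hyper): ``p_case > p_control``, the mirror image.

Methylated read counts are Binomial(C, p) given the proportions.  Because the
Beta priors are conjugate, the proportions integrate out in closed form and
each locus contributes a tractable marginal factor to the posterior of the
genome-wide membership vector.  The only coupling between loci comes from a
Dirichlet-multinomial prior on the membership labels.

All arithmetic is carried out in log space via log-gamma.  The binomial
coefficients are identical across the three group hypotheses for a given
locus and cancel from every posterior ratio; they are excluded unless
explicitly requested (``include_coefficients=True``, used when comparing
against direct numerical integration).
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
from scipy import integrate, special, stats

from .types import BetaParams, Hyperparameters, LocusCounts

__all__ = [
    "log_marginal_equal",
    "log_marginal_hypo",
    "log_marginal_hyper",
    "beta_order_probability",
    "log_partition_prior",
    "compute_log_marginals",
    "log_posterior_unnormalized",
    "enumerate_exact_posterior",
]

# P(X<Y) is clamped away from 0 and 1 before taking logs so that the marginal
# of a strongly ordered locus stays finite in the Metropolis-Hastings ratio.
_ORDER_PROB_FLOOR = 1e-300
_ORDER_PROB_CEIL = 1.0 - 1e-16

# closed-form order probability is used when all shapes are integers and each
# shape sum is at most this; beyond it adaptive quadrature takes over
_CLOSED_FORM_MAX_SHAPE_SUM = 50


def _log_binom_coefficients(locus: LocusCounts) -> float:
    """Sum of log binomial coefficients over every replicate of the locus."""
    total = 0.0
    for cov, meth in ((locus.coverage_case, locus.meth_case),
                      (locus.coverage_control, locus.meth_control)):
        total += float(
            (special.gammaln(cov + 1)
             - special.gammaln(meth + 1)
             - special.gammaln(cov - meth + 1)).sum()
        )
    return total


def log_marginal_equal(
    locus: LocusCounts,
    hyper: Hyperparameters | None = None,
    include_coefficients: bool = False,
) -> float:
    """Log marginal factor of one locus under the equal-methylated group.

    Both conditions share a single proportion ``p ~ Beta(alpha1, beta1)``;
    integrating it against the binomial likelihood gives
    ``B(alpha1 + M, beta1 + N) / B(alpha1, beta1)`` with ``M`` and ``N`` the
    pooled methylated / unmethylated totals over all replicates of both
    conditions.
    """
    hyper = hyper or Hyperparameters()
    m = locus.meth_case_total + locus.meth_control_total
    n = locus.unmeth_case_total + locus.unmeth_control_total
    val = float(
        special.betaln(hyper.alpha1 + m, hyper.beta1 + n)
        - special.betaln(hyper.alpha1, hyper.beta1)
    )
    if include_coefficients:
        val += _log_binom_coefficients(locus)
    return val


def _log_marginal_directional(
    locus: LocusCounts,
    alpha: float,
    beta: float,
    direction: str,
    include_coefficients: bool,
) -> float:
    m1, n1 = locus.meth_case_total, locus.unmeth_case_total
    m2, n2 = locus.meth_control_total, locus.unmeth_control_total
    val = float(
        special.betaln(alpha + m1, beta + n1)
        + special.betaln(alpha + m2, beta + n2)
        - 2.0 * special.betaln(alpha, beta)
    )
    x = BetaParams(alpha + m1, beta + n1)
    y = BetaParams(alpha + m2, beta + n2)
    p_lt = beta_order_probability(x, y)
    p = p_lt if direction == "lt" else 1.0 - p_lt
    p = min(max(p, _ORDER_PROB_FLOOR), _ORDER_PROB_CEIL)
    val += math.log(2.0) + math.log(p)
    if include_coefficients:
        val += _log_binom_coefficients(locus)
    return val


def log_marginal_hypo(
    locus: LocusCounts,
    hyper: Hyperparameters | None = None,
    include_coefficients: bool = False,
) -> float:
    """Log marginal factor under the hypo-methylated group (case < control).

    The truncated product-Beta prior yields per-condition Beta-binomial
    factors times the order term ``2 P(X < Y)`` with
    ``X ~ Beta(alpha2 + M_case, beta2 + N_case)`` and
    ``Y ~ Beta(alpha2 + M_control, beta2 + N_control)``.
    """
    hyper = hyper or Hyperparameters()
    return _log_marginal_directional(
        locus, hyper.alpha2, hyper.beta2, "lt", include_coefficients
    )


def log_marginal_hyper(
    locus: LocusCounts,
    hyper: Hyperparameters | None = None,
    include_coefficients: bool = False,
) -> float:
    """Log marginal factor under the hyper-methylated group (case > control)."""
    hyper = hyper or Hyperparameters()
    return _log_marginal_directional(
        locus, hyper.alpha3, hyper.beta3, "gt", include_coefficients
    )


def _order_probability_closed_form(x: BetaParams, y: BetaParams) -> float:
    # P(Y > X) for integer shapes, via the standard finite sum
    #   sum_{i=0}^{a_y - 1} B(a_x + i, b_x + b_y) / [(b_y + i) B(1+i, b_y) B(a_x, b_x)]
    ay = int(round(y.a))
    terms = np.arange(ay)
    log_terms = (
        special.betaln(x.a + terms, x.b + y.b)
        - np.log(y.b + terms)
        - special.betaln(1.0 + terms, y.b)
        - special.betaln(x.a, x.b)
    )
    if log_terms.size == 0:
        return 0.0
    return float(np.exp(special.logsumexp(log_terms)))


def _order_probability_quadrature(x: BetaParams, y: BetaParams) -> float:
    # P(X < Y) = int f_X(t) (1 - F_Y(t)) dt with the regularized incomplete Beta
    def integrand(t: float) -> float:
        return stats.beta.pdf(t, x.a, x.b) * (1.0 - special.betainc(y.a, y.b, t))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            integrand, 0.0, 1.0, epsabs=1e-13, epsrel=1e-12, limit=500
        )
    if not np.isfinite(val) or err > 1e-8:
        raise ArithmeticError(
            f"order-probability quadrature did not converge (value={val}, err={err})"
        )
    return min(max(val, 0.0), 1.0)


def beta_order_probability(x: BetaParams, y: BetaParams, method: str = "auto") -> float:
    """``P(X < Y)`` for independent ``X ~ Beta(x)`` and ``Y ~ Beta(y)``.

    ``method='auto'`` uses an exact finite-sum closed form when all four
    shapes are integers with per-distribution shape sums at most 50 and
    adaptive quadrature otherwise; ``'closed'`` and ``'quad'`` force one path.
    """
    if not isinstance(x, BetaParams):
        x = BetaParams(*x)
    if not isinstance(y, BetaParams):
        y = BetaParams(*y)
    integer_shapes = all(
        abs(v - round(v)) < 1e-12 for v in (x.a, x.b, y.a, y.b)
    )
    if method == "closed" or (
        method == "auto"
        and integer_shapes
        and x.a + x.b <= _CLOSED_FORM_MAX_SHAPE_SUM
        and y.a + y.b <= _CLOSED_FORM_MAX_SHAPE_SUM
    ):
        if not integer_shapes:
            raise ValueError("closed-form order probability needs integer shapes")
        return _order_probability_closed_form(x, y)
    if method not in ("auto", "quad"):
        raise ValueError(f"unknown method {method!r}")
    return _order_probability_quadrature(x, y)


def log_partition_prior(counts, hyper: Hyperparameters | None = None) -> float:
    """Log prior probability of a membership vector with group sizes ``counts``.

    Marginalizing the Dirichlet-distributed group probabilities out of the
    multinomial membership prior gives
    ``B(k0 + l0, k1 + l1, k2 + l2) / B(k0, k1, k2)`` with the three-argument
    Beta function ``B(a, b, c) = Gamma(a)Gamma(b)Gamma(c)/Gamma(a+b+c)``.
    """
    hyper = hyper or Hyperparameters()
    l = np.asarray(counts, dtype=float)
    if l.shape != (3,):
        raise ValueError("counts must be a triple (l0, l1, l2)")
    if (l < 0).any():
        raise ValueError("group counts must be non-negative")
    k = hyper.dirichlet
    return float(
        special.gammaln(k + l).sum()
        - special.gammaln((k + l).sum())
        - special.gammaln(k).sum()
        + special.gammaln(k.sum())
    )


def compute_log_marginals(
    data: list[LocusCounts],
    hyper: Hyperparameters | None = None,
    include_coefficients: bool = False,
) -> np.ndarray:
    """Per-locus log marginal factors under the three groups, shape (L, 3).

    This cache is computed once; the sampler evaluates every posterior ratio
    from differences of its rows plus the partition-prior count change.
    """
    hyper = hyper or Hyperparameters()
    out = np.empty((len(data), 3), dtype=float)
    for i, locus in enumerate(data):
        out[i, 0] = log_marginal_equal(locus, hyper, include_coefficients)
        out[i, 1] = log_marginal_hypo(locus, hyper, include_coefficients)
        out[i, 2] = log_marginal_hyper(locus, hyper, include_coefficients)
    if not np.isfinite(out).all():
        raise ArithmeticError("non-finite log marginal encountered")
    return out


def log_posterior_unnormalized(
    membership,
    log_g: np.ndarray,
    hyper: Hyperparameters | None = None,
) -> float:
    """Unnormalized log posterior of a full membership vector.

    ``sum_i log_g[i, I_i]`` plus the log Dirichlet-multinomial prior of the
    group sizes; equal to the log posterior up to the constant binomial
    coefficient product and the normalizing constant.
    """
    hyper = hyper or Hyperparameters()
    membership = np.asarray(membership, dtype=np.int64)
    if membership.ndim != 1 or membership.shape[0] != log_g.shape[0]:
        raise ValueError("membership length must match the marginal cache")
    if membership.size and (membership.min() < 0 or membership.max() > 2):
        raise ValueError("membership labels must be in {0, 1, 2}")
    counts = np.bincount(membership, minlength=3)
    lik = float(log_g[np.arange(membership.size), membership].sum())
    return lik + log_partition_prior(counts, hyper)


def enumerate_exact_posterior(
    data: list[LocusCounts],
    hyper: Hyperparameters | None = None,
    max_loci: int = 10,
    log_g: np.ndarray | None = None,
) -> np.ndarray:
    """Exact per-locus posterior membership probabilities by enumeration.

    Enumerates all ``3**L`` membership vectors and normalizes; intended as a
    testing oracle for the sampler, hence the hard cap on ``L``.
    Returns an ``(L, 3)`` array whose rows sum to one.
    """
    hyper = hyper or Hyperparameters()
    L = len(data) if data is not None else log_g.shape[0]
    if L > max_loci:
        raise ValueError(
            f"enumeration over 3^{L} states refused (cap is {max_loci} loci)"
        )
    if log_g is None:
        log_g = compute_log_marginals(data, hyper)
    states = np.array(
        list(itertools.product((0, 1, 2), repeat=L)), dtype=np.int64
    )  # (3^L, L)
    lp = log_g[np.arange(L)[None, :], states].sum(axis=1)
    counts = np.stack([(states == j).sum(axis=1) for j in range(3)], axis=1)
    k = hyper.dirichlet
    lp += (
        special.gammaln(k[None, :] + counts).sum(axis=1)
        - special.gammaln(k.sum() + L)
        - special.gammaln(k).sum()
        + special.gammaln(k.sum())
    )
    lp -= special.logsumexp(lp)
    w = np.exp(lp)
    marg = np.empty((L, 3), dtype=float)
    for j in range(3):
        marg[:, j] = w @ (states == j)
    marg /= marg.sum(axis=1, keepdims=True)
    return marg
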