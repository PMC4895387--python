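"""Unit tests for the collapsed marginal likelihoods, the ordered-Beta
probability, the partition prior and the enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from methylpartition import (
    BetaParams,
    Hyperparameters,
    LocusCounts,
    beta_order_probability,
    compute_log_marginals,
    enumerate_exact_posterior,
    log_marginal_equal,
    log_marginal_hyper,
    log_marginal_hypo,
    log_partition_prior,
    log_posterior_unnormalized,
)
from .conftest import random_small_locus


def quadrature_marginals(locus, hyper):
    """Direct numerical integration of prior x likelihood for one locus.

    Independent of the closed-form implementation: the binomial product is
    evaluated pointwise and integrated over the shared proportion (equal
    group) or the ordered region of the unit square (hypo / hyper groups).
    """

    def binprod(p1, p2):
        v = 1.0
        for c, m in zip(locus.coverage_case, locus.meth_case):
            v *= stats.binom.pmf(m, c, p1)
        for c, m in zip(locus.coverage_control, locus.meth_control):
            v *= stats.binom.pmf(m, c, p2)
        return v

    eq, _ = integrate.quad(
        lambda p: binprod(p, p) * stats.beta.pdf(p, hyper.alpha1, hyper.beta1),
        0, 1, epsabs=1e-13,
    )
    prior2 = lambda p1, p2: (
        2.0
        * stats.beta.pdf(p1, hyper.alpha2, hyper.beta2)
        * stats.beta.pdf(p2, hyper.alpha2, hyper.beta2)
    )
    hypo, _ = integrate.dblquad(
        lambda p2, p1: prior2(p1, p2) * binprod(p1, p2),
        0, 1, lambda p1: p1, lambda p1: 1, epsabs=1e-12,
    )
    prior3 = lambda p1, p2: (
        2.0
        * stats.beta.pdf(p1, hyper.alpha3, hyper.beta3)
        * stats.beta.pdf(p2, hyper.alpha3, hyper.beta3)
    )
    hyperm, _ = integrate.dblquad(
        lambda p2, p1: prior3(p1, p2) * binprod(p1, p2),
        0, 1, lambda p1: 0, lambda p1: p1, epsabs=1e-12,
    )
    return eq, hypo, hyperm


class TestEqualMarginal:
    def test_single_read_closed_form(self, hyper):
        # one methylated case read, one unmethylated control read:
        # B(2, 2) / B(1, 1) = 1/6 (coefficients are all one here)
        lc = LocusCounts([1], [1], [1], [0])
        assert log_marginal_equal(lc, hyper, include_coefficients=True) == pytest.approx(
            math.log(1 / 6), abs=1e-12
        )

    def test_empty_data_contributes_unit_factor(self, hyper):
        lc = LocusCounts([0], [0], [0], [0])
        assert log_marginal_equal(lc, hyper) == pytest.approx(0.0, abs=1e-12)
        assert log_marginal_hypo(lc, hyper) == pytest.approx(
            math.log(2 * 0.5), abs=1e-12
        )  # order term is exactly 1/2 on identical Beta laws

    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            Hyperparameters(alpha1=0.0)
        with pytest.raises(ValueError):
            Hyperparameters(k2=-1.0)


class TestDirectionalMarginals:
    def test_hypo_worked_example(self, hyper):
        # case 0/1, control 1/1: per-condition factors B(1,2) B(2,1) = 1/4,
        # order term 2 P(Beta(1,2) < Beta(2,1)) = 2 * 5/6 -> total 5/12
        lc = LocusCounts([1], [0], [1], [1])
        assert log_marginal_hypo(lc, hyper, include_coefficients=True) == pytest.approx(
            math.log(5 / 12), abs=1e-10
        )

    def test_hyper_mirror_example(self, hyper):
        lc = LocusCounts([1], [1], [1], [0])
        assert log_marginal_hyper(lc, hyper, include_coefficients=True) == pytest.approx(
            math.log(5 / 12), abs=1e-10
        )

    def test_symmetric_data_makes_directions_equal(self, hyper):
        lc = LocusCounts([5, 7], [2, 3], [5, 7], [2, 3])
        assert log_marginal_hypo(lc, hyper) == pytest.approx(
            log_marginal_hyper(lc, hyper), abs=1e-10
        )

    def test_ordered_data_favors_matching_direction(self, hyper):
        lc = LocusCounts([20, 20], [1, 2], [20, 20], [18, 19])
        assert log_marginal_hypo(lc, hyper) > log_marginal_hyper(lc, hyper)
        mirrored = lc.swapped()
        assert log_marginal_hyper(mirrored, hyper) > log_marginal_equal(mirrored, hyper)

    def test_label_swap_identity(self, hyper):
        rng = np.random.default_rng(7)
        for _ in range(10):
            lc = random_small_locus(rng)
            assert log_marginal_hypo(lc, hyper) == pytest.approx(
                log_marginal_hyper(lc.swapped(), hyper), abs=1e-12
            )

    def test_monotone_evidence_gap(self, hyper):
        # moving pooled case counts down and control counts up can only
        # strengthen the hypo-vs-hyper evidence
        gaps = []
        for shift in range(0, 11):
            lc = LocusCounts([20, 20], [10 - shift, 10 - shift],
                            [20, 20], [10 + (shift + 1) // 2, 10 + shift // 2])
            gaps.append(log_marginal_hypo(lc, hyper) - log_marginal_hyper(lc, hyper))
        assert all(b >= a - 1e-12 for a, b in zip(gaps, gaps[1:]))


class TestQuadratureOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_marginals_match_direct_integration(self, seed, hyper):
        rng = np.random.default_rng(seed)
        for _ in range(5):
            lc = random_small_locus(rng)
            eq, hypo, hyperm = quadrature_marginals(lc, hyper)
            for oracle, impl in (
                (eq, log_marginal_equal(lc, hyper, include_coefficients=True)),
                (hypo, log_marginal_hypo(lc, hyper, include_coefficients=True)),
                (hyperm, log_marginal_hyper(lc, hyper, include_coefficients=True)),
            ):
                assert math.exp(impl) == pytest.approx(oracle, rel=1e-8)

    def test_non_uniform_prior_also_matches(self):
        hp = Hyperparameters(alpha1=2.0, beta1=3.0, alpha2=1.5, beta2=2.5,
                             alpha3=2.5, beta3=1.5)
        lc = LocusCounts([4, 3], [1, 2], [5, 2], [3, 1])
        eq, hypo, hyperm = quadrature_marginals(lc, hp)
        assert math.exp(log_marginal_equal(lc, hp, True)) == pytest.approx(eq, rel=1e-7)
        assert math.exp(log_marginal_hypo(lc, hp, True)) == pytest.approx(hypo, rel=1e-7)
        assert math.exp(log_marginal_hyper(lc, hp, True)) == pytest.approx(hyperm, rel=1e-7)


class TestOrderProbability:
    def test_exchangeable_shapes_give_half(self):
        assert beta_order_probability(BetaParams(3, 4), BetaParams(3, 4)) == pytest.approx(
            0.5, abs=1e-10
        )

    def test_closed_form_worked_example(self):
        # P(Beta(1,2) < Beta(2,1)) = int 2(1-t)(1-t^2) dt = 5/6
        assert beta_order_probability(BetaParams(1, 2), BetaParams(2, 1)) == pytest.approx(
            5 / 6, abs=1e-12
        )

    @pytest.mark.parametrize(
        "x,y", [((1, 2), (2, 1)), ((3, 5), (4, 2)), ((10, 10), (12, 8)), ((1, 1), (6, 2))]
    )
    def test_closed_form_agrees_with_quadrature(self, x, y):
        closed = beta_order_probability(BetaParams(*x), BetaParams(*y), method="closed")
        quad = beta_order_probability(BetaParams(*x), BetaParams(*y), method="quad")
        assert closed == pytest.approx(quad, abs=1e-10)

    @given(
        a1=st.floats(0.2, 30), b1=st.floats(0.2, 30),
        a2=st.floats(0.2, 30), b2=st.floats(0.2, 30),
    )
    def test_complement_identity(self, a1, b1, a2, b2):
        x, y = BetaParams(a1, b1), BetaParams(a2, b2)
        total = beta_order_probability(x, y) + beta_order_probability(y, x)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            BetaParams(0.0, 1.0)
        with pytest.raises(ValueError):
            beta_order_probability((1.0, -2.0), (1.0, 1.0))


class TestPartitionPrior:
    def test_empty_partition_is_certain(self, hyper):
        assert log_partition_prior((0, 0, 0), hyper) == pytest.approx(0.0, abs=1e-14)

    def test_single_locus_uniform_over_groups(self, hyper):
        assert log_partition_prior((1, 0, 0), hyper) == pytest.approx(
            math.log(1 / 3), abs=1e-12
        )

    def test_two_locus_value_and_normalization(self, hyper):
        assert log_partition_prior((2, 0, 0), hyper) == pytest.approx(
            math.log(1 / 6), abs=1e-12
        )
        total = sum(
            math.exp(log_partition_prior(np.bincount(v, minlength=3), hyper))
            for v in itertools.product((0, 1, 2), repeat=2)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_negative_counts_rejected(self, hyper):
        with pytest.raises(ValueError):
            log_partition_prior((-1, 1, 0), hyper)


class TestPosteriorAndEnumeration:
    def test_single_locus_composition(self, hyper):
        lc = LocusCounts([3], [1], [4], [2])
        log_g = compute_log_marginals([lc], hyper)
        assert log_posterior_unnormalized([0], log_g, hyper) == pytest.approx(
            log_g[0, 0] + math.log(1 / 3), abs=1e-12
        )

    def test_locus_permutation_invariance(self, hyper, ambiguous_fixture):
        log_g = compute_log_marginals(ambiguous_fixture, hyper)
        membership = np.array([0, 1, 2, 1, 0, 2])
        base = log_posterior_unnormalized(membership, log_g, hyper)
        perm = np.array([3, 0, 5, 1, 4, 2])
        assert log_posterior_unnormalized(
            membership[perm], log_g[perm], hyper
        ) == pytest.approx(base, abs=1e-10)

    def test_length_mismatch_rejected(self, hyper):
        log_g = compute_log_marginals([LocusCounts([3], [1], [4], [2])], hyper)
        with pytest.raises(ValueError):
            log_posterior_unnormalized([0, 1], log_g, hyper)

    def test_marginals_normalize(self, hyper, ambiguous_fixture):
        marg = enumerate_exact_posterior(ambiguous_fixture, hyper)
        assert np.allclose(marg.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_locus_has_equal_directional_mass(self, hyper):
        lc = LocusCounts([4, 5], [2, 2], [4, 5], [2, 2])
        marg = enumerate_exact_posterior([lc], hyper)
        assert marg[0, 1] == pytest.approx(marg[0, 2], abs=1e-12)

    def test_partition_prior_couples_loci(self, hyper):
        weak = LocusCounts([4, 3], [1, 1], [4, 4], [2, 3])
        strong_hypo = LocusCounts([6, 6], [0, 0], [6, 6], [6, 6])
        alone = enumerate_exact_posterior([weak], hyper)[0]
        with_strong = enumerate_exact_posterior([weak, strong_hypo], hyper)[0]
        assert not np.allclose(alone, with_strong, atol=1e-4)
        # the hypo-heavy companion pulls the weak locus toward hypo
        assert with_strong[1] > alone[1]

    def test_label_swap_exchanges_directional_marginals(self, hyper, ambiguous_fixture):
        marg = enumerate_exact_posterior(ambiguous_fixture, hyper)
        swapped = enumerate_exact_posterior(
            [lc.swapped() for lc in ambiguous_fixture], hyper
        )
        assert np.allclose(marg[:, 0], swapped[:, 0], atol=1e-12)
        assert np.allclose(marg[:, 1], swapped[:, 2], atol=1e-12)
        assert np.allclose(marg[:, 2], swapped[:, 1], atol=1e-12)

    def test_enumeration_cap(self, hyper):
        data = [LocusCounts([1], [0], [1], [1])] * 11
        with pytest.raises(ValueError, match="cap"):
            enumerate_exact_posterior(data, hyper)
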