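"""Differential-kinetics bootstrap, allelic-imbalance binomial, independence
chi-square, and BH correction, against closed-form or hand-computed oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from allelicburst import (
    KineticParams,
    apply_technical_noise,
    binomial_imbalance_test,
    bootstrap_differential_test,
    fdr_adjust,
    independence_test,
    simulate_true_expression,
)
from allelicburst.classify import CategoryCounts


def _bursty_counts(n=300, seed=0, s=60.0):
    k = KineticParams(0.2, 0.2, s)
    _, ya, _, yb = simulate_true_expression(k, k, np.ones(n), seed=seed)
    return ya.astype(float), yb.astype(float)


class TestBootstrapDifferential:
    def test_identical_alleles_give_p_one(self):
        qa, _ = _bursty_counts(seed=1)
        r = bootstrap_differential_test(qa, qa.copy(), n_boot=200, seed=2)
        assert r.observed_diff_freq == 0.0
        assert r.observed_diff_size == 0.0
        assert r.p_freq == 1.0 and r.p_size == 1.0

    def test_p_values_never_zero_and_reproducible(self):
        qa, qb = _bursty_counts(seed=3)
        r1 = bootstrap_differential_test(qa, qb, n_boot=300, seed=7)
        r2 = bootstrap_differential_test(qa, qb, n_boot=300, seed=7)
        assert 0 < r1.p_freq <= 1 and 0 < r1.p_size <= 1
        assert r1.p_freq == r2.p_freq and r1.p_size == r2.p_size
        assert r1.p_freq >= 1.0 / r1.n_valid_boot

    def test_allele_swap_symmetry(self):
        qa, qb = _bursty_counts(seed=4)
        r1 = bootstrap_differential_test(qa, qb, n_boot=300, seed=9)
        r2 = bootstrap_differential_test(qb, qa, n_boot=300, seed=9)
        assert r1.p_freq == r2.p_freq and r1.p_size == r2.p_size

    def test_power_at_strong_frequency_alternative(self, mouse_noise):
        ka = KineticParams(0.2, 0.2, 50.0)
        kb = KineticParams(2.0, 0.2, 50.0)
        rng = np.random.default_rng(21)
        rejected = tested = 0
        for _ in range(25):
            _, ya, _, yb = simulate_true_expression(ka, kb, np.ones(100), seed=rng)
            qa, _ = apply_technical_noise(ya, mouse_noise, seed=rng)
            qb, _ = apply_technical_noise(yb, mouse_noise, seed=rng)
            try:
                r = bootstrap_differential_test(
                    qa, qb, noise=mouse_noise, n_boot=500, seed=rng
                )
            except ValueError:
                continue
            tested += 1
            rejected += r.p_freq <= 0.05
        assert tested >= 20
        assert rejected / tested > 0.8

    def test_non_estimable_observed_alleles_rejected(self):
        flat = np.full(100, 10.0)  # constitutive-like: inversion degenerate
        with pytest.raises(ValueError, match="not estimable"):
            bootstrap_differential_test(flat, flat.copy(), n_boot=50, seed=0)


class TestBinomialImbalance:
    def test_balanced_totals_give_p_one(self):
        assert binomial_imbalance_test([50], [50]) == 1.0

    def test_extreme_imbalance_closed_form(self):
        p = binomial_imbalance_test(np.zeros(5), np.array([20, 20, 20, 20, 20]))
        assert p == pytest.approx(2 * 0.5**100, rel=1e-9)

    def test_sixty_forty_exact_tail_sum(self):
        # independent oracle: sum the Binomial(100, 0.5) pmf over the
        # two-sided rejection region
        p = binomial_imbalance_test([60], [40])
        pmf = stats.binom.pmf(np.arange(101), 100, 0.5)
        expected = pmf[pmf <= pmf[60] * (1 + 1e-12)].sum()
        assert p == pytest.approx(expected, rel=1e-10)
        assert p == pytest.approx(0.0569, abs=2e-4)

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="zero total"):
            binomial_imbalance_test([0], [0])


class TestIndependence:
    def test_exact_independence_gives_zero_statistic(self):
        r = independence_test(CategoryCounts(25, 25, 25, 25))
        assert r.chi2 == 0.0 and r.p == 1.0 and r.direction == "none"

    def test_coordinated_hand_example(self):
        r = independence_test(CategoryCounts(40, 10, 10, 40))
        assert r.chi2 == pytest.approx(36.0)
        assert r.p == pytest.approx(1.97e-9, rel=0.01)
        assert r.direction == "coordinated"
        assert np.allclose(r.expected, 25.0)

    def test_repulsed_mirror_case(self):
        r = independence_test(CategoryCounts(10, 40, 40, 10))
        assert r.chi2 == pytest.approx(36.0)
        assert r.direction == "repulsed"

    def test_small_sample_and_degenerate_marginals_skipped(self):
        assert independence_test(CategoryCounts(5, 5, 5, 4)).skipped
        assert independence_test(CategoryCounts(0, 0, 10, 40)).skipped  # p_A = 1

    def test_expected_counts_sum_to_observed(self):
        r = independence_test(CategoryCounts(30, 12, 18, 25))
        assert sum(r.expected) == pytest.approx(sum(r.observed))


class TestFDR:
    def test_all_ones_never_flagged(self):
        q, flags = fdr_adjust(np.ones(10))
        assert not flags.any()
        assert np.allclose(q, 1.0)

    def test_bh_hand_example_flags_all_four(self):
        q, flags = fdr_adjust([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert flags.all()
        assert np.all(q <= 0.05)

    def test_single_p_is_its_own_q(self):
        q, flags = fdr_adjust([0.04])
        assert q[0] == pytest.approx(0.04) and flags[0]

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_q_monotone_in_p_property(self, p):
        """BH q-values are a monotone transform of the p-values."""
        q, _ = fdr_adjust(np.asarray(p))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_q_monotone_in_p_and_nan_passthrough(self):
        p = np.array([0.2, np.nan, 0.001, 0.5, 0.01])
        q, flags = fdr_adjust(p)
        assert np.isnan(q[1]) and not flags[1]
        order = np.argsort(p[~np.isnan(p)])
        qs = q[~np.isnan(p)][order]
        assert np.all(np.diff(qs) >= -1e-12)
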