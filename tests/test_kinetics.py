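"""Moment algebra, histogram repiling, and the kinetic estimator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allelicburst import (
    KineticParams,
    NoiseParams,
    estimate_allele_kinetics,
    factorial_moments,
    forward_moments,
    invert_moments,
    repile,
    simulate_true_expression,
)
from allelicburst.kinetics import BurstKineticsEstimator, Moments


class TestMomentInversion:
    def test_exact_round_trip_at_reference_point(self):
        m = forward_moments(0.2, 0.2, 50.0)
        k_on, k_off, s, ok = invert_moments(*m)
        assert ok
        assert (k_on, k_off, s) == pytest.approx((0.2, 0.2, 50.0), rel=1e-8)

    def test_round_trip_on_random_grid(self):
        rng = np.random.default_rng(123)
        k_on = rng.uniform(0.05, 5.0, 100)
        k_off = rng.uniform(0.05, 5.0, 100)
        s = rng.uniform(5.0, 500.0, 100)
        ko, kf, ss, ok = invert_moments(*forward_moments(k_on, k_off, s))
        assert np.all(ok)
        assert np.allclose(ko, k_on, rtol=1e-6)
        assert np.allclose(kf, k_off, rtol=1e-6)
        assert np.allclose(ss, s, rtol=1e-6)

    def test_pure_poisson_moments_not_estimable(self):
        # constitutive limit: factorial moments of Poisson(25) make the
        # closed-form denominators vanish
        lam = 25.0
        _, _, _, ok = invert_moments(lam, lam**2, lam**3)
        assert not ok


class TestRepiling:
    def test_identity_noise_is_identity_on_histograms(self):
        q = np.array([0, 0, 3, 3, 3, 7.0])
        h = repile(q, NoiseParams.identity())
        assert np.array_equal(h.support, [3.0, 7.0])
        assert np.array_equal(h.weights, [3.0, 1.0])
        assert h.n_zero == 2.0

    def test_half_detection_doubles_weights_until_floor(self):
        # expit(0) = 0.5 so each observed cell stands for two true cells
        q = np.array([0, 0, 0, 5.0])
        h = repile(q, NoiseParams(1.0, 1.0, 0.0, 0.0))
        assert np.allclose(h.weights, [2.0])
        assert h.n_zero == 2.0

    def test_hand_example_with_amplification(self):
        q = np.array([0] * 5 + [2] * 3 + [4] * 2, dtype=float)
        h = repile(q, NoiseParams(2.0, 1.0, 40.0, 0.0))
        assert np.allclose(h.support, [1.0, 2.0])
        assert np.allclose(h.weights, [3.0, 2.0])
        assert h.n_zero == 5.0

    def test_weight_conservation_with_flooring(self):
        # heavy reweighting would exceed the cell count; total must stay n
        q = np.array([1.0, 2.0, 3.0, 4.0])
        h = repile(q, NoiseParams(1.0, 1.0, -3.0, 0.0))
        assert h.total_weight() == pytest.approx(4.0)
        assert h.n_zero == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 30), min_size=2, max_size=60),
        kappa=st.floats(-3.0, 3.0),
        tau=st.floats(-1.0, 1.5),
        alpha=st.floats(0.2, 3.0),
        beta=st.floats(0.5, 1.5),
    )
    def test_weight_conservation_property(self, counts, kappa, tau, alpha, beta):
        """Total repiled weight always equals the number of cells."""
        q = np.asarray(counts, dtype=float)
        h = repile(q, NoiseParams(alpha, beta, kappa, tau))
        assert h.total_weight() == pytest.approx(q.size, rel=1e-9)
        assert h.n_zero >= 0.0
        assert np.all(h.weights >= 0.0)

    def test_weight_conservation_generic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            q = rng.poisson(3, size=50).astype(float)
            kappa = rng.uniform(-2, 2)
            h = repile(q, NoiseParams(1.0, 1.0, kappa, 0.3))
            assert h.total_weight() == pytest.approx(50.0)

    def test_invalid_noise_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            NoiseParams(0.0, 1.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="beta"):
            NoiseParams(1.0, -1.0, 0.0, 0.0)

    def test_eta_normalisation_scales_support(self):
        q = np.array([4.0, 4.0])
        h = repile(q, NoiseParams.identity(), eta=np.array([1.0, 2.0]))
        assert np.allclose(np.sort(h.support), [2.0, 4.0])


class TestFactorialMoments:
    def test_all_zero_histogram_gives_zero_moments(self):
        h = repile(np.zeros(10), NoiseParams.identity())
        m = factorial_moments(h)
        assert m.as_tuple() == (0.0, 0.0, 0.0)

    def test_monte_carlo_moments_match_forward_formulas(self):
        k = KineticParams(0.2, 0.2, 50.0)
        n = 100_000
        _, y, _, _ = simulate_true_expression(k, k, np.ones(n), seed=11)
        h = repile(y.astype(float), NoiseParams.identity())
        m = factorial_moments(h)
        m1, m2, m3 = forward_moments(k.k_on, k.k_off, k.s)
        yf = y.astype(float)
        for sample, expected, stat in (
            (m.m1, m1, yf),
            (m.m2, m2, yf * (yf - 1)),
            (m.m3, m3, yf * (yf - 1) * (yf - 2)),
        ):
            se = stat.std(ddof=1) / np.sqrt(n)
            assert abs(sample - expected) < 3 * se

    def test_doubling_phi_halves_first_moment(self):
        h = repile(np.array([2.0, 4.0, 0.0]), NoiseParams.identity())
        m1 = factorial_moments(h, phi=np.ones(3)).m1
        m2 = factorial_moments(h, phi=2 * np.ones(3)).m1
        assert m2 == pytest.approx(m1 / 2)


class TestKineticEstimator:
    def test_identical_alleles_get_identical_estimates(self):
        rng = np.random.default_rng(3)
        q = rng.poisson(5, size=200).astype(float)
        est = estimate_allele_kinetics(q, q.copy(), n_boot=0)
        assert est["A"].k_on == est["B"].k_on
        assert est["A"].burst_size == est["B"].burst_size

    def test_bursty_gene_recovery_without_noise(self):
        k = KineticParams(0.2, 0.2, 100.0)
        _, ya, _, yb = simulate_true_expression(k, k, np.ones(2000), seed=13)
        est = estimate_allele_kinetics(ya.astype(float), yb.astype(float), n_boot=0)
        for allele in ("A", "B"):
            e = est[allele]
            assert e.estimable
            assert e.burst_frequency == pytest.approx(0.2, rel=0.5)
            assert e.burst_size == pytest.approx(500.0, rel=0.5)

    def test_bootstrap_reports_se_and_ci(self):
        k = KineticParams(0.2, 0.2, 60.0)
        _, ya, _, yb = simulate_true_expression(k, k, np.ones(300), seed=14)
        est = estimate_allele_kinetics(
            ya.astype(float), yb.astype(float), n_boot=100, seed=1
        )
        e = est["A"]
        assert e.n_boot_valid > 50 and not e.unstable
        lo, hi = e.ci["burst_frequency"]
        assert lo < e.k_on < hi or e.se["burst_frequency"] > 0

    def test_sklearn_estimator_fit_surface(self):
        k = KineticParams(0.3, 0.3, 50.0)
        _, ya, _, yb = simulate_true_expression(k, k, np.ones(400), seed=15)
        X = np.column_stack([ya, yb]).astype(float)
        mdl = BurstKineticsEstimator(n_boot=0).fit(X)
        assert mdl.estimate_A_.estimable
        assert mdl.get_params()["n_boot"] == 0
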