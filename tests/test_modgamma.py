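"""The modified gamma density: evaluation, fitting, residuals, trends."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tailchase import io as tio
from tailchase import modgamma as tm


def sample_distribution(params, n, seed, label=""):
    rng = np.random.default_rng(seed)
    dens = tm.density_array(params)
    reads = rng.choice(len(dens), size=n, p=dens)
    return tio.build_distribution(reads.astype(float), label=label)


class TestDensity:
    def test_protection_saturates_over_pab1_footprint(self):
        assert round(tm.protection_factor(20), 2) == 0.96

    def test_protection_saturation_invariant(self):
        i = np.arange(20, 251)
        assert (tm.protection_factor(i) >= 0.95).all()

    def test_shape_zero_is_geometric(self):
        p = tm.ModGammaParams(gamma_shape=0.0, gamma_rate=0.05)
        d = tm.density_array(p)
        ratios = d[1:50] / d[0:49]
        np.testing.assert_allclose(ratios, np.exp(-0.05), rtol=1e-12)

    def test_right_arm_ratio_is_exp_minus_rate(self):
        p = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        d = tm.density_array(p)
        i = np.arange(40, 100)
        ratios = d[i + 1] / d[i]
        np.testing.assert_allclose(ratios, np.exp(-0.10), atol=1e-3)

    def test_density_zero_at_origin(self):
        p = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        assert tm.modgamma_density(0, p) == 0.0

    def test_outside_support_errors(self):
        p = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        with pytest.raises(ValueError, match="support"):
            tm.modgamma_density(251, p)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(0.1, 20.0),
        st.floats(0.01, 0.5),
    )
    def test_normalization_for_any_params(self, shape, rate):
        p = tm.ModGammaParams(gamma_shape=shape, gamma_rate=rate)
        assert abs(tm.density_array(p).sum() - 1.0) < 1e-9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            tm.ModGammaParams(gamma_shape=-1.0, gamma_rate=0.1)
        with pytest.raises(ValueError):
            tm.ModGammaParams(gamma_shape=1.0, gamma_rate=0.0)


class TestFit:
    def test_parameter_recovery_50k_reads(self):
        truth = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        d = sample_distribution(truth, 50_000, seed=7)
        fit = tm.fit_modgamma(d)
        assert fit.fit.converged
        assert abs(fit.gamma_shape - 3.7) / 3.7 < 0.05
        assert abs(fit.gamma_rate - 0.10) / 0.10 < 0.05

    def test_geometric_histogram_fits_near_zero_shape(self):
        truth = tm.ModGammaParams(gamma_shape=0.0, gamma_rate=0.05)
        d = sample_distribution(truth, 50_000, seed=3)
        fit = tm.fit_modgamma(d)
        assert fit.gamma_shape <= 0.1

    def test_single_bin_errors(self):
        d = tio.build_distribution([60.0] * 100)
        with pytest.raises(ValueError, match="support"):
            tm.fit_modgamma(d)

    def test_below_minimum_reads_errors(self):
        d = tio.build_distribution(np.linspace(10, 100, 20))
        with pytest.raises(ValueError, match="below minimum reads"):
            tm.fit_modgamma(d)

    def test_fit_idempotence(self):
        truth = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        counts = np.round(tm.density_array(truth) * 1e7)
        d = tio.TailDistribution(counts)
        fit = tm.fit_modgamma(d)
        assert abs(fit.gamma_shape - 3.7) < 1e-3
        assert abs(fit.gamma_rate - 0.10) < 1e-5


class TestStats:
    def test_classical_gamma_limit_mean(self):
        # small beta: tanh(beta*i)^shape -> (beta*i)^shape, so the density
        # approaches the classical gamma with mean (shape + 1) / rate
        p = tm.ModGammaParams(gamma_shape=3.0, gamma_rate=0.05, beta=1e-3)
        stats = tm.distribution_stats(p)
        assert abs(stats["mean"] - 80.0) / 80.0 < 0.02

    def test_mean_decreases_with_rate(self):
        lo = tm.distribution_stats(tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.05))
        hi = tm.distribution_stats(tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10))
        assert hi["mean"] < lo["mean"]

    def test_stats_match_sample_moments(self):
        truth = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        d = sample_distribution(truth, 50_000, seed=5)
        fit = tm.fit_modgamma(d)
        stats = tm.distribution_stats(fit)
        i = d.support.astype(float)
        emp_mean = float((d.density * i).sum())
        emp_var = float((d.density * (i - emp_mean) ** 2).sum())
        assert abs(stats["mean"] - emp_mean) < 1.0
        assert abs(stats["variance"] - emp_var) / emp_var < 0.05


class TestRightArmRate:
    def test_recovers_rate_on_exact_density(self):
        p = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        d = tio.TailDistribution(np.round(tm.density_array(p) * 1e7))
        assert abs(tm.right_arm_rate(d) - 0.10) < 1e-3

    def test_robust_to_peak_region_mixture(self):
        # a mixture of profiles differing in gamma_shape broadens the peak
        # but shares the right arm; the arm estimator stays on target
        mix = np.zeros(251)
        for shape in (3.0, 3.5, 4.0, 4.5):
            mix += tm.density_array(tm.ModGammaParams(gamma_shape=shape, gamma_rate=0.10))
        d = tio.TailDistribution(np.round(mix / mix.sum() * 1e7))
        assert abs(tm.right_arm_rate(d) - 0.10) < 5e-3

    def test_sparse_window_returns_nan(self):
        counts = np.zeros(251)
        counts[10] = 100
        counts[42] = 1
        assert np.isnan(tm.right_arm_rate(tio.TailDistribution(counts)))


class TestNewSynthesisResidual:
    @staticmethod
    def mixture_distribution():
        main = tm.density_array(tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10))
        peak = np.zeros_like(main)
        peak[48:53] = [0.1, 0.2, 0.4, 0.2, 0.1]
        mix = 0.8 * main + 0.2 * peak
        return tio.TailDistribution(np.round(mix * 1e6))

    def test_exact_model_gives_zero_fraction(self):
        p = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        d = tio.TailDistribution(np.round(tm.density_array(p) * 1e6))
        fit = tm.fit_modgamma(d)
        r = tm.new_synthesis_residual(d, fit)
        assert r.fraction_new == 0.0

    def test_mixture_recovers_fraction_and_mode(self):
        d = self.mixture_distribution()
        fit = tm.fit_modgamma(d)
        r = tm.new_synthesis_residual(d, fit)
        assert r.fraction_new == pytest.approx(0.20, abs=0.03)
        assert 40 <= r.mode <= 60

    def test_depletion_like_sample_below_floor(self):
        # sampled pure modgamma (no new synthesis): detection stays near 0
        truth = tm.ModGammaParams(gamma_shape=3.7, gamma_rate=0.10)
        d = sample_distribution(truth, 100_000, seed=11)
        fit = tm.fit_modgamma(d)
        r = tm.new_synthesis_residual(d, fit)
        assert r.fraction_new <= 0.02

    def test_component_mass_equals_fraction(self):
        d = self.mixture_distribution()
        fit = tm.fit_modgamma(d)
        r = tm.new_synthesis_residual(d, fit)
        assert r.fitted_new_mrna.sum() == pytest.approx(r.fraction_new, abs=1e-9)

    def test_refit_baseline_detects_bump_on_heterogeneous_aggregate(self):
        # on a multi-shape aggregate the plain fit absorbs part of the bump;
        # the masked refit with free amplitude does not
        mix = np.zeros(251)
        for shape in (3.0, 3.5, 4.0, 4.5):
            mix += 0.25 * tm.density_array(
                tm.ModGammaParams(gamma_shape=shape, gamma_rate=0.10)
            )
        bump = np.exp(-0.5 * ((np.log2(np.arange(251).clip(1)) - np.log2(50)) / 0.35) ** 2)
        bump[:1] = 0
        bump /= bump.sum()
        d = tio.TailDistribution(np.round((0.85 * mix + 0.15 * bump) * 1e7))
        fit = tm.fit_modgamma(d)
        robust = tm.new_synthesis_residual(d, fit, refit_baseline=True)
        assert robust.fraction_new == pytest.approx(0.15, abs=0.05)
        assert 40 <= robust.mode <= 60


class TestParamTrend:
    @staticmethod
    def params_at(shape, rate):
        return tm.ModGammaParams(gamma_shape=shape, gamma_rate=rate)

    def test_constant_params_flat_trend(self):
        pts = [(t, self.params_at(3.7, 0.10)) for t in (0.0, 2.0, 4.0, 8.0)]
        trend = tm.fit_param_trend(pts)
        b0, b1 = trend.coefficients["gamma_rate"]
        assert b1 == pytest.approx(0.0, abs=1e-12)
        assert b0 == pytest.approx(0.10)

    def test_linear_trend_recovered_within_2_se(self, rng):
        times = np.array([0.0, 1.0, 2.0, 4.0, 6.0, 8.0])
        true_slope = 0.004
        pts = [
            (
                float(t),
                self.params_at(3.7, 0.10 + true_slope * t + rng.normal(0, 0.002)),
            )
            for t in times
        ]
        trend = tm.fit_param_trend(pts)
        _, slope = trend.coefficients["gamma_rate"]
        _, se = trend.standard_errors["gamma_rate"]
        assert abs(slope - true_slope) <= 2 * se

    def test_too_few_points_errors(self):
        pts = [(0.0, self.params_at(3.7, 0.1)), (1.0, self.params_at(3.7, 0.1))]
        with pytest.raises(ValueError):
            tm.fit_param_trend(pts)

    def test_predicted_distributions_track_generating_medians(self):
        # params generated exactly on a line: predicted densities reproduce
        # the generating median trajectory within 2 A at each timepoint
        times = (0.0, 2.0, 4.0, 6.0, 8.0)
        gen = {t: self.params_at(3.7 + 0.01 * t, 0.10 + 0.003 * t) for t in times}
        trend = tm.fit_param_trend([(t, p) for t, p in gen.items()])
        for t, truth in gen.items():
            pred, ok = trend.predict(t)
            assert ok
            med_true = tm.distribution_stats(truth)["median"]
            med_pred = tm.distribution_stats(pred)["median"]
            assert abs(med_pred - med_true) < 2.0

    def test_extrapolation_flagged(self):
        pts = [(t, self.params_at(3.7, 0.10)) for t in (0.0, 2.0, 4.0)]
        trend = tm.fit_param_trend(pts)
        _, ok = trend.predict(100.0)
        assert not ok
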