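"""Evolution operators, decay adjustment, half-lives, rate conversion."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import poisson

from tailchase import io as tio
from tailchase import kinetics as tk
from tailchase import modgamma as tm


def modgamma_counts(shape=3.7, rate=0.10, scale=1e6):
    p = tm.ModGammaParams(gamma_shape=shape, gamma_rate=rate)
    return tm.density_array(p) * scale


class TestOdeEvolve:
    def test_zero_time_identity(self):
        x0 = modgamma_counts()
        out = tk.ode_evolve(x0, k=1.0, t_grid=[0.0])[0]
        np.testing.assert_allclose(out, x0, atol=1e-10)

    def test_delta_source_gives_shifted_poisson(self):
        x0 = np.zeros(251)
        x0[60] = 1.0
        out = tk.ode_evolve(x0, k=1.0, t_grid=[1.0])[0]
        i = np.arange(1, 61)
        expected = poisson.pmf(60 - i, 1.0)
        np.testing.assert_allclose(out[1:61], expected, atol=1e-9)

    def test_mass_non_increasing(self):
        rng = np.random.default_rng(2)
        x0 = rng.random(251)
        x0[0] = 0.0
        levels = tk.ode_evolve(x0, k=2.0, t_grid=[0.0, 1.0, 2.0, 5.0])
        masses = levels.sum(axis=1)
        assert (np.diff(masses) <= 1e-9).all()

    def test_negative_k_errors(self):
        with pytest.raises(ValueError):
            tk.ode_evolve(np.ones(10), k=-1.0, t_grid=[1.0])


class TestAnalyticEvolve:
    def test_alpha_zero_identity(self):
        x0 = modgamma_counts()
        np.testing.assert_allclose(tk.analytic_evolve(x0, 0.0), x0, atol=1e-12)

    def test_matches_ode_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(3):
            x0 = rng.random(251)
            x0[0] = 0.0
            ana = tk.analytic_evolve(x0, 2.0)
            ode = tk.ode_evolve(x0, k=1.0, t_grid=[2.0])[0]
            assert np.abs(ana - ode).max() < 1e-8

    def test_semigroup_property(self):
        x0 = modgamma_counts()
        once = tk.analytic_evolve(tk.analytic_evolve(x0, 1.5), 2.5)
        direct = tk.analytic_evolve(x0, 4.0)
        assert np.abs(once - direct).max() < 1e-8

    def test_protected_attenuates_short_tails_only(self):
        x0 = modgamma_counts()
        plain = tk.analytic_evolve(x0, 4.0)
        prot = tk.analytic_evolve(x0, 4.0, protected=True)
        short = np.arange(1, 11)
        assert (prot[short] < plain[short]).all()
        far = np.arange(100, 251)
        rel = np.abs(prot[far] - plain[far]) / np.clip(plain[far], 1e-300, None)
        assert rel.max() < 1e-6

    def test_fixed_protection_exponent(self):
        x0 = modgamma_counts()
        fixed = tk.analytic_evolve(x0, 4.0, protected=True, protection_exponent=2.0)
        expected = tk.analytic_evolve(x0, 4.0) * tm.protection_factor(
            np.arange(251)
        ) ** 2.0
        expected[0] = 0.0
        np.testing.assert_allclose(fixed, expected, rtol=1e-12)

    def test_negative_alpha_errors(self):
        with pytest.raises(ValueError):
            tk.analytic_evolve(np.ones(10), -0.5)


def make_series(timepoints, dists, recovery):
    return tk.ChaseSeries(
        timepoints=np.asarray(timepoints, dtype=float),
        distributions=dists,
        recovery_coeff=np.asarray(recovery, dtype=float),
    )


class TestAdjustForDecay:
    def test_unit_coefficients_no_change(self):
        d = tio.TailDistribution(modgamma_counts())
        s = make_series([0.0, 1.0], [d, d], [1.0, 1.0])
        adj = tk.adjust_for_decay(s)
        np.testing.assert_allclose(adj.absolute[1], d.density)

    def test_half_coefficient_halves_levels(self):
        d = tio.TailDistribution(modgamma_counts())
        s = make_series([0.0, 8.0], [d, d], [1.0, 0.5])
        adj = tk.adjust_for_decay(s)
        np.testing.assert_allclose(adj.absolute[1], adj.absolute[0] / 2)

    def test_missing_coefficients_error(self):
        d = tio.TailDistribution(modgamma_counts())
        s = tk.ChaseSeries(np.array([0.0]), [d])
        with pytest.raises(ValueError, match="recovery"):
            tk.adjust_for_decay(s)


def protected_series(k=10.9, gamma=0.10, timepoints=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0)):
    """Eq.-6 evolution of a modified gamma profile, absolute bookkeeping."""
    x0 = modgamma_counts(rate=gamma, scale=1.0)
    dists, recovery = [], []
    for t in timepoints:
        x = tk.analytic_evolve(x0, k * t, protected=True)
        recovery.append(x.sum())
        dists.append(tio.TailDistribution(x / x.sum() * 1e6, time_min=t))
    return make_series(timepoints, dists, recovery)


class TestPositionHalfLives:
    def test_recovers_expected_asymptote(self):
        k, gamma = 10.9, 0.10
        series = protected_series(k, gamma)
        est = tk.position_half_lives(tk.adjust_for_decay(series))
        expected_s = np.log(2) / (k * (1 - np.exp(-gamma))) * 60.0
        assert abs(est.half_life_s - expected_s) / expected_s < 0.15

    def test_doubling_k_halves_half_life(self):
        one = tk.position_half_lives(tk.adjust_for_decay(protected_series(k=10.9)))
        two = tk.position_half_lives(tk.adjust_for_decay(protected_series(k=21.8)))
        assert two.half_life_s == pytest.approx(one.half_life_s / 2, rel=0.05)

    def test_too_few_timepoints_error(self):
        s = protected_series(timepoints=(0.0, 1.0))
        with pytest.raises(ValueError, match="timepoints"):
            tk.position_half_lives(tk.adjust_for_decay(s))

    def test_duality_half_life_times_rate(self):
        est = tk.position_half_lives(tk.adjust_for_decay(protected_series()))
        r_app = np.log(2) / (est.half_life_s / 60.0)
        assert est.half_life_s * r_app == pytest.approx(60.0 * np.log(2))


class TestEstimateTimeShift:
    def test_constructed_offset_recovered(self):
        series = protected_series(timepoints=(0.0, 1.0, 2.0, 4.0, 6.0, 8.0))
        adj = tk.adjust_for_decay(series)
        # a control that is 2.67 min fresher than the trend at t=0:
        # levels lie on the fitted exponentials extrapolated to t = -2.67
        t_fit = adj.timepoints
        X = adj.absolute
        control = np.zeros(X.shape[1])
        for i in range(40, 81):
            A = np.column_stack([np.ones_like(t_fit), t_fit])
            coef, *_ = np.linalg.lstsq(A, np.log(X[:, i]), rcond=None)
            control[i] = np.exp(coef[0] + (-coef[1]) * 2.67)
        shift, interior = tk.estimate_time_shift(control, adj)
        assert interior
        assert shift == pytest.approx(2.67, abs=0.05)

    def test_control_on_trend_gives_zero(self):
        series = protected_series()
        adj = tk.adjust_for_decay(series)
        control = adj.absolute[0]
        shift, _ = tk.estimate_time_shift(control, adj)
        assert abs(shift) < 0.2

    def test_boundary_optimum_flagged(self):
        series = protected_series()
        adj = tk.adjust_for_decay(series)
        control = adj.absolute[0]
        _, interior = tk.estimate_time_shift(control, adj, grid=(3.0, 6.0, 0.01))
        assert not interior


class TestApparentToMicroscopic:
    def test_headline_constants_small_gamma(self):
        est = tk.apparent_to_microscopic(1.09, 0.1, small_gamma_approx=True)
        assert est.microscopic_rate == pytest.approx(10.9)

    def test_large_gamma_no_correction(self):
        est = tk.apparent_to_microscopic(1.0, 20.0)
        assert est.microscopic_rate == pytest.approx(1.0, rel=1e-6)

    def test_gamma_ln2_doubles(self):
        est = tk.apparent_to_microscopic(1.0, np.log(2))
        assert est.microscopic_rate == pytest.approx(2.0)

    def test_monotone_decreasing_in_gamma(self):
        rates = [
            tk.apparent_to_microscopic(1.0, g).microscopic_rate
            for g in (0.05, 0.1, 0.2, 0.5)
        ]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_zero_gamma_errors(self):
        with pytest.raises(ValueError):
            tk.apparent_to_microscopic(1.0, 0.0)

    def test_half_life_duality(self):
        est = tk.apparent_to_microscopic(1.09, 0.1)
        assert est.adenosine_half_life_s * est.apparent_rate == pytest.approx(
            60.0 * np.log(2)
        )


class TestAlphaMatch:
    def test_self_consistency_recovers_k(self):
        k = 10.0
        x0 = modgamma_counts(scale=1.0)
        timepoints = (2.0, 4.0, 6.0, 8.0)
        dists, recovery = [], []
        for t in timepoints:
            x = tk.analytic_evolve(x0, k * t, protected=True)
            recovery.append(x.sum())
            dists.append(tio.TailDistribution(x / x.sum() * 1e6, time_min=t))
        series = make_series(timepoints, dists, recovery)
        adj = tk.adjust_for_decay(series)
        match = tk.alpha_match(x0, adj, alpha_grid=np.arange(0.0, 100.0, 0.1))
        assert match.slope_k == pytest.approx(k, abs=0.2)
        assert match.pearson_r > 0.99

    def test_observed_equals_initial_gives_zero(self):
        x0 = modgamma_counts(scale=1.0)
        d = tio.TailDistribution(x0 * 1e6)
        series = make_series([0.0], [d], [1.0])
        adj = tk.adjust_for_decay(series)
        match = tk.alpha_match(x0, adj, alpha_grid=np.arange(0.0, 5.0, 0.05))
        assert match.alpha_best[0] == 0.0

    def test_identical_timepoints_tie_flagged(self):
        x0 = modgamma_counts(scale=1.0)
        d = tio.TailDistribution(x0 * 1e6, time_min=1.0)
        d2 = tio.TailDistribution(x0 * 1e6, time_min=2.0)
        series = make_series([1.0, 2.0], [d, d2], [1.0, 1.0])
        adj = tk.adjust_for_decay(series)
        match = tk.alpha_match(x0, adj, alpha_grid=np.arange(0.0, 5.0, 0.05))
        assert match.ties

    def test_empty_grid_errors(self):
        x0 = modgamma_counts(scale=1.0)
        d = tio.TailDistribution(x0 * 1e6)
        series = make_series([1.0], [d], [1.0])
        adj = tk.adjust_for_decay(series)
        with pytest.raises(ValueError, match="grid"):
            tk.alpha_match(x0, adj, alpha_grid=np.array([]))

    def test_log_lsq_window_variant(self):
        k = 10.0
        x0 = modgamma_counts(scale=1.0)
        timepoints = (2.0, 4.0)
        dists, recovery = [], []
        for t in timepoints:
            x = tk.analytic_evolve(x0, k * t, protected=True)
            recovery.append(x.sum())
            dists.append(tio.TailDistribution(x / x.sum() * 1e6, time_min=t))
        adj = tk.adjust_for_decay(make_series(timepoints, dists, recovery))
        match = tk.alpha_match(
            x0,
            adj,
            alpha_grid=np.arange(0.0, 60.0, 0.1),
            metric="log_lsq",
            window=(40, 80),
        )
        assert match.slope_k == pytest.approx(k, rel=0.05)

    def test_bad_window_errors(self):
        x0 = modgamma_counts(scale=1.0)
        d = tio.TailDistribution(x0 * 1e6)
        adj = tk.adjust_for_decay(make_series([1.0], [d], [1.0]))
        with pytest.raises(ValueError, match="window"):
            tk.alpha_match(
                x0, adj, alpha_grid=np.arange(0.0, 2.0, 0.5), window=(40, 400)
            )
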