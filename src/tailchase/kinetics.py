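"""Deadenylation kinetics: the coupled ODE system, its analytic solution,
decay adjustment, per-position adenosine half-lives, time-shift estimation,
and the microscopic-versus-apparent rate conversion.

Distributive deadenylation at constant microscopic rate k moves tail mass
one adenosine at a time:

    dx_i/dt = -k * x_i + k * x_{i+1}        (x_{N+1} = 0, length 0 = sink)

whose closed form is a Poisson convolution in alpha = k * t:

    x_i(t) = e^(-alpha) * sum_{j>=i} n(j) * alpha^(j-i) / (j-i)!

optionally attenuated by the decapping protection prefactor
tanh(beta*i)^alpha.  A population-level fit of per-position levels observes
not k but the apparent rate k_app = k * (1 - e^(-gamma_rate)), because
adjacent tail-length abundances sit in a geometric ratio e^(-gamma_rate) on
the distribution's right arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import pearsonr, poisson

from .io import TailDistribution
from .modgamma import DEFAULT_BETA

__all__ = [
    "ChaseSeries",
    "PositionHalfLife",
    "AsymptoteEstimate",
    "RateEstimate",
    "AlphaMatch",
    "ode_evolve",
    "analytic_evolve",
    "adjust_for_decay",
    "position_half_lives",
    "estimate_time_shift",
    "apparent_to_microscopic",
    "alpha_match",
]


@dataclass
class ChaseSeries:
    """Ordered chase timepoints with tail distributions and pA+ recovery.

    ``recovery_coeff[j]`` is the amount of pA+ RNA recovered at timepoint j
    relative to the control, used to place normalized densities on an
    absolute (decay-aware) scale.  ``absolute`` is populated by
    :func:`adjust_for_decay`; densities stay untouched.
    """

    timepoints: np.ndarray
    distributions: list[TailDistribution]
    recovery_coeff: np.ndarray | None = None
    replicate_id: str = ""
    absolute: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if len(self.timepoints) != len(self.distributions):
            raise ValueError("one distribution per timepoint required")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.recovery_coeff is not None:
            self.recovery_coeff = np.asarray(self.recovery_coeff, dtype=float)
            if len(self.recovery_coeff) != len(self.timepoints):
                raise ValueError("one recovery coefficient per timepoint required")
            if np.any(self.recovery_coeff <= 0) or np.any(self.recovery_coeff > 1.5):
                raise ValueError("recovery coefficients must lie in (0, 1.5]")


def ode_evolve(
    n0: TailDistribution | np.ndarray,
    k: float,
    t_grid: Sequence[float],
    rtol: float = 1e-12,
    atol: float = 1e-14,
) -> np.ndarray:
    """Integrate the coupled tail-shortening ODEs numerically.

    Returns the array of absolute levels x_i at each time in ``t_grid``
    (rows), the brute-force oracle for :func:`analytic_evolve`.  The
    length-0 bin is an absorbing sink: mass flowing out of bin 1 leaves the
    tracked system.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    x0 = n0.counts if isinstance(n0, TailDistribution) else np.asarray(n0, dtype=float)

    def rhs(_t: float, x: np.ndarray) -> np.ndarray:
        dx = -k * x
        dx[:-1] += k * x[1:]
        dx[0] = 0.0  # sink bin: holds no mass, passes none back
        return dx

    y0 = x0.astype(float).copy()
    y0[0] = 0.0
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or t_grid.max() == 0.0:
        # degenerate span: solve_ivp cannot integrate over (0, 0)
        return np.tile(y0, (t_grid.size, 1))
    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid.max()) if t_grid.size else 0.0),
        y0,
        t_eval=t_grid,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y.T


def analytic_evolve(
    n0: TailDistribution | np.ndarray,
    alpha: float,
    protected: bool = False,
    beta: float = DEFAULT_BETA,
    protection_exponent: float | None = None,
) -> np.ndarray:
    """Closed-form tail evolution after alpha = k*t rounds of deadenylation.

    Evaluates the Poisson-convolution solution; with ``protected=True`` the
    result is additionally attenuated by tanh(beta*i)^alpha, modeling
    decapping of poorly protected short tails.  The exponent alpha couples
    protection strength to elapsed rounds; ``protection_exponent``
    substitutes a fixed exponent instead.  Returns absolute levels (mass
    reaching length 0 is absorbed, so totals shrink with alpha).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    x0 = n0.counts if isinstance(n0, TailDistribution) else np.asarray(n0, dtype=float)
    n = len(x0)
    src = x0.astype(float).copy()
    src[0] = 0.0
    w = poisson.pmf(np.arange(n), alpha)
    # x_i = sum_j n(j) * Pois(j - i; alpha) — a correlation of n with the pmf
    x = np.correlate(src, w, mode="full")[n - 1 :]
    if protected:
        i = np.arange(n, dtype=float)
        exponent = alpha if protection_exponent is None else protection_exponent
        x = x * np.tanh(beta * i) ** exponent
    x[0] = 0.0
    return x


def adjust_for_decay(series: ChaseSeries) -> ChaseSeries:
    """Scale each timepoint's distribution by its pA+ recovery coefficient.

    Produces the absolute (decay-aware) per-position levels used by
    :func:`position_half_lives`; normalized densities are kept as-is in the
    distributions themselves.
    """
    if series.recovery_coeff is None:
        raise ValueError("recovery coefficients missing")
    absolute = np.array(
        [c * d.density for c, d in zip(series.recovery_coeff, series.distributions)]
    )
    return ChaseSeries(
        timepoints=series.timepoints,
        distributions=series.distributions,
        recovery_coeff=series.recovery_coeff,
        replicate_id=series.replicate_id,
        absolute=absolute,
    )


@dataclass
class PositionHalfLife:
    position: int
    half_life_s: float
    se_s: float
    n_timepoints: int


@dataclass
class AsymptoteEstimate:
    """Transcriptomic adenosine half-life over the plateau window.

    ``half_life_s`` is the bootstrap mean of per-position half-lives over
    the window (the stable summary); ``curve_fit_asymptote_s`` is the
    asymptote of an exponential-plus-constant curve of half-life versus
    position, reported as a diagnostic (it is unstable when the curve is
    tilted rather than plateaued).
    """

    half_life_s: float
    ci_low_s: float
    ci_high_s: float
    window: tuple[int, int]
    curve_fit_asymptote_s: float
    per_position: list[PositionHalfLife]
    skipped_positions: list[int]


def position_half_lives(
    adjusted_series: ChaseSeries,
    positions: Sequence[int] | None = None,
    window: tuple[int, int] = (40, 80),
    include_t0: bool = True,
    n_boot: int = 1000,
    seed: int = 0,
) -> AsymptoteEstimate:
    """Per-position exponential fits of absolute levels and their asymptote.

    For each tail position i, the log absolute level is regressed on time
    (log-linear least squares over timepoints with positive level; at least
    2 usable points).  The transcriptomic adenosine half-life is the
    bootstrap mean over positions inside ``window`` with a percentile CI.
    ``include_t0=False`` drops the first timepoint (e.g. an unshifted
    control) from the fits.
    """
    if adjusted_series.absolute is None:
        raise ValueError("run adjust_for_decay first")
    t = adjusted_series.timepoints
    X = adjusted_series.absolute
    if not include_t0:
        t, X = t[1:], X[1:]
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    if positions is None:
        positions = range(1, 81)
    results: list[PositionHalfLife] = []
    skipped: list[int] = []
    for i in positions:
        y = X[:, i]
        ok = y > 0
        if ok.sum() < 2:
            skipped.append(int(i))
            continue
        tt, yy = t[ok], np.log(y[ok])
        A = np.column_stack([np.ones_like(tt), tt])
        coef, *_ = np.linalg.lstsq(A, yy, rcond=None)
        slope = coef[1]
        if slope >= 0:
            skipped.append(int(i))
            continue
        dof = max(ok.sum() - 2, 1)
        resid = yy - A @ coef
        se_slope = float(
            np.sqrt(((resid**2).sum() / dof) / ((tt - tt.mean()) ** 2).sum())
        )
        hl_s = np.log(2) / (-slope) * 60.0
        se_s = hl_s * se_slope / (-slope)
        results.append(PositionHalfLife(int(i), float(hl_s), se_s, int(ok.sum())))
    lo, hi = window
    in_win = np.array([r.half_life_s for r in results if lo <= r.position <= hi])
    if in_win.size == 0:
        raise ValueError("no usable positions inside the asymptote window")
    rng = np.random.default_rng(seed)
    boot = np.array(
        [rng.choice(in_win, size=in_win.size, replace=True).mean() for _ in range(n_boot)]
    )
    # diagnostic exponential-plus-asymptote fit over all fitted positions
    pos = np.array([r.position for r in results], dtype=float)
    hls = np.array([r.half_life_s for r in results])
    asym = float("nan")
    if len(pos) >= 4:
        from scipy.optimize import curve_fit

        try:
            popt, _ = curve_fit(
                lambda i, c, a, b: c + a * np.exp(-b * i),
                pos,
                hls,
                p0=[float(in_win.mean()), float(hls[0] - hls[-1]), 0.05],
                bounds=([0.0, -np.inf, 1e-4], [np.inf, np.inf, 1.0]),
                maxfev=20000,
            )
            asym = float(popt[0])
        except (RuntimeError, ValueError):
            pass
    return AsymptoteEstimate(
        half_life_s=float(boot.mean()),
        ci_low_s=float(np.quantile(boot, 0.025)),
        ci_high_s=float(np.quantile(boot, 0.975)),
        window=window,
        curve_fit_asymptote_s=asym,
        per_position=results,
        skipped_positions=skipped,
    )


def estimate_time_shift(
    control_levels: np.ndarray,
    adjusted_series: ChaseSeries,
    positions: Sequence[int] = range(40, 81),
    grid: tuple[float, float, float] = (-1.0, 6.0, 0.01),
) -> tuple[float, bool]:
    """Forward time shift that lands the control on the depletion trend.

    Per-position exponentials x_i(t) = A_i * e^(-r_i t) are fitted on the
    depletion timepoints only.  A control that is fresher than the
    depletion trend sits at trend time -s; the returned s > 0 is the
    forward shift that lands it on the trend, found by minimizing
    sum_i (ln A_i + r_i s - ln c_i)^2 over control levels c_i (grid search
    plus closed-form refinement).  Boundary optima are flagged (second
    element False).
    """
    if adjusted_series.absolute is None:
        raise ValueError("run adjust_for_decay first")
    t = adjusted_series.timepoints
    X = adjusted_series.absolute
    control_levels = np.asarray(control_levels, dtype=float)
    logs_a, rates, logs_c = [], [], []
    for i in positions:
        y = X[:, i]
        c = control_levels[i]
        if (y > 0).all() and c > 0:
            A = np.column_stack([np.ones_like(t), t])
            coef, *_ = np.linalg.lstsq(A, np.log(y), rcond=None)
            if coef[1] < 0:
                logs_a.append(coef[0])
                rates.append(-coef[1])
                logs_c.append(np.log(c))
    if not logs_a:
        raise ValueError("no overlapping usable positions")
    a = np.array(logs_a)
    r = np.array(rates)
    c = np.array(logs_c)
    lo, hi, step = grid
    ss = np.arange(lo, hi + step / 2, step)
    errs = ((a[None, :] + r[None, :] * ss[:, None] - c[None, :]) ** 2).sum(axis=1)
    s_grid = float(ss[int(np.argmin(errs))])
    # closed-form optimum of the quadratic objective
    s_star = float((r * (c - a)).sum() / (r**2).sum())
    interior = lo + step < s_grid < hi - step
    return (s_star if interior else s_grid), bool(interior)


@dataclass
class RateEstimate:
    """Apparent and microscopic deadenylation rates (adenosines/min)."""

    apparent_rate: float
    microscopic_rate: float
    gamma_rate_used: float
    adenosine_half_life_s: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    small_gamma_approx: bool = False

    def __post_init__(self) -> None:
        if self.microscopic_rate < self.apparent_rate - 1e-12:
            raise ValueError("microscopic rate cannot be below the apparent rate")


def apparent_to_microscopic(
    r_app: float,
    gamma_rate: float,
    small_gamma_approx: bool = False,
    ci: tuple[float, float] | None = None,
) -> RateEstimate:
    """Convert an apparent rate to the microscopic rate, k = k_app/(1-e^-gamma).

    With ``small_gamma_approx`` the denominator is gamma_rate itself
    (1 - e^-gamma ~= gamma for small gamma).  Confidence limits scale
    multiplicatively.
    """
    if r_app <= 0:
        raise ValueError("apparent rate must be > 0")
    if gamma_rate <= 0:
        raise ValueError("gamma_rate must be > 0")
    factor = gamma_rate if small_gamma_approx else 1.0 - np.exp(-gamma_rate)
    micro = r_app / factor
    scale = micro / r_app
    lo, hi = (ci if ci else (float("nan"), float("nan")))
    return RateEstimate(
        apparent_rate=float(r_app),
        microscopic_rate=float(micro),
        gamma_rate_used=float(gamma_rate),
        adenosine_half_life_s=float(np.log(2) / r_app * 60.0),
        ci_low=float(lo) * scale if ci else float("nan"),
        ci_high=float(hi) * scale if ci else float("nan"),
        small_gamma_approx=small_gamma_approx,
    )


@dataclass
class AlphaMatch:
    """Virtual-deadenylation matching of observed snapshots."""

    timepoints: np.ndarray
    alpha_best: np.ndarray
    pearson_r: float
    slope_k: float
    ties: list[int]


def alpha_match(
    initial_dist: TailDistribution | np.ndarray,
    observed_series: ChaseSeries,
    alpha_grid: np.ndarray | None = None,
    metric: str = "lsq",
    use_absolute: bool = True,
    protected: bool = True,
    window: tuple[int, int] | None = None,
) -> AlphaMatch:
    """Match each observed timepoint to the best number of virtual rounds.

    The initial distribution is evolved by each alpha on the grid (Eq.-6
    style protected evolution by default) and compared against the observed
    snapshot — decay-adjusted absolute levels when ``use_absolute`` (the
    recovery coefficients exist precisely to put snapshots on an absolute
    scale), normalized densities otherwise.  ``metric`` is "lsq" (sum of
    squared differences, default), "log_lsq" (squared differences of log
    levels over positions where the observed level is positive; weights
    every position equally instead of letting the largest levels dominate)
    or "pearson".  ``window`` restricts the comparison to a closed position
    range, e.g. the quasi-stationary right arm where the closed-form
    evolution is most faithful.  The regression slope of alpha_best against
    time (through the origin) estimates k; ties break toward the smaller
    alpha and are flagged.
    """
    x0 = (
        initial_dist.density
        if isinstance(initial_dist, TailDistribution)
        else np.asarray(initial_dist, dtype=float)
    )
    t = observed_series.timepoints
    if use_absolute:
        if observed_series.absolute is None:
            raise ValueError("use_absolute requires adjust_for_decay output")
        obs = observed_series.absolute
    else:
        obs = np.array([d.density for d in observed_series.distributions])
    if alpha_grid is None:
        alpha_grid = np.arange(0.0, 15.0001, 0.05)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if alpha_grid.size == 0:
        raise ValueError("empty alpha grid")
    evolved = np.array([analytic_evolve(x0, a, protected=protected) for a in alpha_grid])
    evolved_density = evolved / np.clip(evolved.sum(axis=1, keepdims=True), 1e-300, None)
    if window is not None:
        lo, hi = int(window[0]), int(window[1])
        if not 0 <= lo < hi < obs.shape[1]:
            raise ValueError(f"window {window!r} outside support")
        sel = slice(lo, hi + 1)
        obs = obs[:, sel]
        evolved = evolved[:, sel]
        evolved_density = evolved_density[:, sel]
    best = np.empty(len(t))
    ties: list[int] = []
    for j in range(len(t)):
        target = obs[j]
        cand = evolved if use_absolute else evolved_density
        if metric == "log_lsq":
            pos = target > 0
            if not pos.any():
                raise ValueError(f"no positive observed levels at timepoint {t[j]}")
            logt = np.log(target[pos])
            logc = np.log(np.clip(cand[:, pos], 1e-300, None))
            scores = ((logc - logt[None, :]) ** 2).sum(axis=1)
            idx = int(np.argmin(scores))
        elif metric == "lsq":
            scores = ((cand - target[None, :]) ** 2).sum(axis=1)
            order = np.argsort(scores, kind="stable")
            idx = int(order[0])
            if len(order) > 1 and np.isclose(scores[order[1]], scores[idx], rtol=0, atol=1e-15):
                idx = int(min(order[0], order[1]))
                ties.append(j)
        elif metric == "pearson":
            scores = np.array([-pearsonr(c, target).statistic for c in cand])
            idx = int(np.argmin(scores))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        best[j] = alpha_grid[idx]
        if j > 0 and np.array_equal(obs[j], obs[j - 1]):
            ties.append(j)  # identical snapshots: later time keeps the smaller alpha
    mask = t > 0
    slope = float((best[mask] * t[mask]).sum() / (t[mask] ** 2).sum()) if mask.any() else 0.0
    r = (
        float(pearsonr(t, best).statistic)
        if len(t) >= 3 and len(set(best)) > 1
        else float("nan")
    )
    return AlphaMatch(t, best, r, slope, ties)
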