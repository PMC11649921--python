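"""End-to-end analysis workflows over a chase run directory.

A run directory is the layout written by :func:`tailchase.synth.write_chase`
(and the expected arrangement for real data): per-(replicate, timepoint)
read tables ``rep{r}_t{t}.tsv`` in the nanopolish-polya dialect, per-replicate
``abundance_rep{r}.tsv`` count tables, ``recovery.tsv`` with the pA+
recovery coefficients, and ``manifest.json`` describing the design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from . import io as tio
from . import kinetics as tk
from . import modgamma as tm
from . import quantile_rates as tq

__all__ = [
    "ChaseRun",
    "load_run",
    "fit_gamma_workflow",
    "screen_timepoints",
    "kinetics_workflow",
    "quantile_rates_workflow",
]


@dataclass
class ChaseRun:
    """A loaded chase run: read tables, abundances, recovery, design."""

    run_dir: Path
    timepoints: np.ndarray
    n_replicates: int
    tables: list[list[tio.TailTable]]  # [replicate][timepoint]
    abundance: list[pd.DataFrame]  # [replicate], timepoint columns "t{t:g}"
    recovery_coeff: np.ndarray
    manifest: dict


def load_run(run_dir: str | Path, qc_policy: Sequence[str] | None = ("PASS",)) -> ChaseRun:
    """Load a chase run directory (see module docstring for the layout)."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    timepoints = np.asarray(manifest["timepoints"], dtype=float)
    n_rep = int(manifest["n_replicates"])
    tables = []
    for rep in range(1, n_rep + 1):
        rep_tables = []
        for t in timepoints:
            path = run_dir / f"rep{rep}_t{t:g}.tsv"
            rep_tables.append(
                tio.read_polya_table(path, qc_policy=qc_policy, time_min=float(t))
            )
        tables.append(rep_tables)
    abundance = [
        pd.read_csv(run_dir / f"abundance_rep{rep}.tsv", sep="\t", index_col=0)
        for rep in range(1, n_rep + 1)
    ]
    rec = pd.read_csv(run_dir / "recovery.tsv", sep="\t")
    return ChaseRun(
        run_dir=run_dir,
        timepoints=timepoints,
        n_replicates=n_rep,
        tables=tables,
        abundance=abundance,
        recovery_coeff=rec["recovery_coeff"].to_numpy(dtype=float),
        manifest=manifest,
    )


def _aggregate_distributions(
    run: ChaseRun, n_max: int = tm.DEFAULT_SUPPORT_MAX
) -> list[tio.TailDistribution]:
    """Replicate-merged, all-transcript tail histograms per timepoint."""
    out = []
    for j, t in enumerate(run.timepoints):
        per_rep = [
            tio.build_distribution(run.tables[rep][j], n_max=n_max, label="aggregate")
            for rep in range(run.n_replicates)
        ]
        out.append(tio.merge_replicates(per_rep))
    return out


def fit_gamma_workflow(
    run: ChaseRun,
    beta: float = tm.DEFAULT_BETA,
    n_max: int = tm.DEFAULT_SUPPORT_MAX,
) -> tuple[pd.DataFrame, tm.ParamTrend]:
    """Fit the modified gamma per timepoint and a linear parameter trend."""
    dists = _aggregate_distributions(run, n_max)
    rows = []
    params_by_time = []
    for t, dist in zip(run.timepoints, dists):
        params = tm.fit_modgamma(dist, beta_fixed=beta)
        rows.append(
            {
                "time_min": float(t),
                "gamma_shape": params.gamma_shape,
                "gamma_rate": params.gamma_rate,
                "se_shape": params.fit.se_shape,
                "se_rate": params.fit.se_rate,
                "sse": params.fit.sse,
                "converged": params.fit.converged,
                "n_reads": dist.n_reads,
            }
        )
        params_by_time.append((float(t), params))
    trend = tm.fit_param_trend(params_by_time)
    return pd.DataFrame(rows), trend


def screen_timepoints(
    run: ChaseRun,
    beta: float = tm.DEFAULT_BETA,
) -> tuple[list[tio.TailDistribution], dict[float, float]]:
    """Per-timepoint new-synthesis diagnostic on the aggregate profiles.

    Fits the modified gamma to each timepoint's aggregate profile and
    reports the residual new-synthesis fraction.  The fraction is a
    diagnostic: the pre-existing new-synthesis cohort deadenylates like
    every other tail, so it is real signal for the mass-erosion
    (quantile) estimates, and the position half-life window sits above
    it for all but the earliest samples.  Returns (aggregate
    distributions, fraction_new by time).
    """
    dists = _aggregate_distributions(run)
    frac_by_time: dict[float, float] = {}
    for t, dist in zip(run.timepoints, dists):
        params = tm.fit_modgamma(dist, beta_fixed=beta)
        residual = tm.new_synthesis_residual(dist, params, refit_baseline=True)
        frac_by_time[float(t)] = residual.fraction_new
    return dists, frac_by_time


def kinetics_workflow(
    run: ChaseRun,
    beta: float = tm.DEFAULT_BETA,
    window: tuple[int, int] = (40, 80),
    alpha_step: float = 0.5,
    seed: int = 0,
) -> dict:
    """Full deadenylation-kinetics chain on the aggregate profile.

    Decay adjustment -> per-position half-lives over the depletion
    timepoints (the control carries new synthesis and is excluded from
    the fits) -> window asymptote -> apparent rate -> microscopic rate
    via the window-mean right-arm gamma_rate -> virtual-deadenylation
    (alpha) matching as a cross-check.
    """
    if len(run.timepoints) < 4:
        raise ValueError("insufficient depletion timepoints (need control + >= 3)")
    dists, frac_by_time = screen_timepoints(run, beta=beta)

    # depletion timepoints only for the position-level fits
    keep = np.array([t > 0 for t in run.timepoints], dtype=bool)
    if keep.sum() < 3:
        raise ValueError("insufficient depletion timepoints (need >= 3 with t > 0)")
    clean = tk.ChaseSeries(
        timepoints=run.timepoints[keep],
        distributions=[d for d, k in zip(dists, keep) if k],
        recovery_coeff=run.recovery_coeff[keep],
    )
    clean_adj = tk.adjust_for_decay(clean)
    asym = tk.position_half_lives(clean_adj, window=window, include_t0=True, seed=seed)
    r_app = float(np.log(2) / (asym.half_life_s / 60.0))

    # window-mean right-arm gamma_rate over the clean modeling timepoints
    # (the right arm is geometric with ratio e^(-gamma_rate); the slope
    # estimator over the half-life window is robust to the peak-region
    # mixture broadening that biases a whole-profile fit)
    gamma_by_time = {
        float(t): tm.right_arm_rate(dist, window=window)
        for t, dist in zip(run.timepoints, dists)
    }
    gamma_window = float(
        np.mean([gamma_by_time[float(t)] for t, k in zip(run.timepoints, keep) if k])
    )
    # the headline conversion uses the small-gamma form of Eq. 8
    # (1 - e^-gamma ~ gamma); the exact form is reported alongside
    est = tk.apparent_to_microscopic(r_app, gamma_window, small_gamma_approx=True)
    est_exact = tk.apparent_to_microscopic(r_app, gamma_window)

    # alpha matching: only the pre-existing pool evolves (the control's
    # new-synthesis component is nuclear and never enters the chase), so
    # the seed is the smooth outlier-masked modified-gamma baseline of the
    # control — the control minus its new-synthesis component, with the
    # sparse far arm denoised — and the recovery coefficients are rescaled
    # to that pool.  Matching is log-least-squares on absolute levels over
    # the half-life window, where the quasi-stationary solution makes the
    # window amplitude decay at gamma_rate per round.
    ctrl_params = tm.fit_modgamma(dists[0], beta_fixed=beta)
    residual = tm.new_synthesis_residual(dists[0], ctrl_params, refit_baseline=True)
    baseline = tm.masked_baseline(dists[0], ctrl_params)
    seed_density = baseline / baseline.sum()
    pool_scale = 1.0 - residual.fraction_new
    match_series = tk.ChaseSeries(
        timepoints=run.timepoints[1:],
        distributions=dists[1:],
        recovery_coeff=run.recovery_coeff[1:] / pool_scale,
    )
    match_adj = tk.adjust_for_decay(match_series)
    alpha_max = 1.5 * est_exact.microscopic_rate * float(run.timepoints.max())
    match = tk.alpha_match(
        seed_density,
        match_adj,
        alpha_grid=np.arange(0.0, alpha_max + alpha_step / 2, alpha_step),
        metric="log_lsq",
        use_absolute=True,
        window=window,
    )
    # gamma_rate drifts upward over the chase, so the observed log-level
    # drop is k * integral(gamma) while the evolved seed decays at its own
    # arm slope gamma_0; rescale each alpha by gamma_0 / running-mean gamma
    # so that alpha = k * t under the quasi-stationary solution
    gamma_seed = tm.right_arm_rate(
        tio.TailDistribution(seed_density * 1e6), window=window
    )
    g_times = np.concatenate([[0.0], run.timepoints[keep]])
    g_values = np.concatenate(
        [[gamma_seed], [gamma_by_time[float(t)] for t in run.timepoints[keep]]]
    )
    alpha_corrected = np.empty_like(match.alpha_best)
    for j, t in enumerate(match.timepoints):
        m = g_times <= float(t) + 1e-9
        g_bar = float(np.trapezoid(g_values[m], g_times[m])) / float(t)
        alpha_corrected[j] = match.alpha_best[j] * gamma_seed / g_bar
    slope_k = float(
        (alpha_corrected * match.timepoints).sum() / (match.timepoints**2).sum()
    )
    pearson_alpha = (
        float(pearsonr(match.timepoints, alpha_corrected).statistic)
        if len(match.timepoints) >= 3 and len(set(alpha_corrected)) > 1
        else float("nan")
    )
    return {
        "adenosine_half_life_s": asym.half_life_s,
        "adenosine_half_life_ci_s": [asym.ci_low_s, asym.ci_high_s],
        "curve_fit_asymptote_s": asym.curve_fit_asymptote_s,
        "apparent_rate_a_per_min": r_app,
        "gamma_rate_window_mean": gamma_window,
        "gamma_rate_by_time": gamma_by_time,
        "microscopic_rate_a_per_min": est.microscopic_rate,
        "microscopic_rate_exact_a_per_min": est_exact.microscopic_rate,
        "new_synthesis_fraction_by_time": frac_by_time,
        "alpha_best_by_time": dict(
            zip(map(float, match.timepoints), map(float, alpha_corrected))
        ),
        "alpha_slope_a_per_min": slope_k,
        "alpha_pearson_r": pearson_alpha,
    }


def replicate_inputs(
    run: ChaseRun, n_max: int = tm.DEFAULT_SUPPORT_MAX
) -> list[dict[str, dict]]:
    """Per-replicate transcript inputs for the quantile-rate estimator.

    Abundances are normalized against the control library of each
    replicate (not per-sample): in a chase the whole pool decays, and
    run-directory read depth tracks input material, so a common scale
    preserves the decay dynamics that per-sample scaling would divide
    out.
    """
    control_col = f"t{run.timepoints[0]:g}"
    out = []
    for rep in range(run.n_replicates):
        norm = tio.normalize_abundance(
            {col: run.abundance[rep][col] for col in run.abundance[rep].columns},
            reference_sample=control_col,
        )
        normalized = {col: tab.normalized for col, tab in norm.items()}
        per_tid: dict[str, dict] = {}
        grouped = [
            dict(tuple(table.records.groupby("transcript_id")))
            for table in run.tables[rep]
        ]
        tids = set().union(*[set(g) for g in grouped])
        for tid in tids:
            lengths = [
                g[tid]["tail_length"].to_numpy(dtype=float) if tid in g else np.empty(0)
                for g in grouped
            ]
            cols = [f"t{t:g}" for t in run.timepoints]
            ab = [
                float(normalized[c].get(tid, np.nan)) if c in normalized else np.nan
                for c in cols
            ]
            per_tid[tid] = {
                "timepoints": run.timepoints,
                "lengths_by_time": lengths,
                "abundances": np.asarray(ab, dtype=float),
            }
        out.append(per_tid)
    return out


def quantile_rates_workflow(
    run: ChaseRun,
    policy: tq.FilterPolicy | None = None,
    groups: dict[str, list[str]] | None = None,
) -> dict:
    """Per-transcript quantile deadenylation + decay rates, plus a pooled
    (all-transcript) deadenylation estimate and group summaries.

    The pooled control quantiles are taken from the control profile with
    its fitted new-synthesis residual removed: the depletion timepoints
    chase the pre-existing pool only, so referencing the raw (mixed)
    control would book the one-off loss of the new-synthesis component
    as deadenylation.  All timepoints contribute by default;
    condition-specific exclusions (e.g. samples known to violate the
    chase design) can be supplied via
    ``policy.deadenylation_exclude_times``.
    """
    policy = policy or tq.FilterPolicy()
    reps = replicate_inputs(run)
    rates = tq.transcript_rate_table(reps, policy=policy)
    summary, corr = tq.group_summary(rates, groups)

    # pooled estimate: all transcripts, replicates pooled per timepoint
    pooled_lengths = [
        np.concatenate([run.tables[rep][j].lengths() for rep in range(run.n_replicates)])
        for j in range(len(run.timepoints))
    ]
    qs = tq.compute_quantiles(
        pooled_lengths, run.timepoints, policy=policy, label="pooled"
    )
    control = _aggregate_distributions(run)[0]
    ctrl_params = tm.fit_modgamma(control, beta_fixed=tm.DEFAULT_BETA)
    residual = tm.new_synthesis_residual(control, ctrl_params, refit_baseline=True)
    if residual.fraction_new > 0:
        cleaned = np.clip(control.density - residual.fitted_new_mrna, 0.0, None)
        cum = np.cumsum(cleaned / cleaned.sum())
        qs.values[0, :] = np.interp(
            np.asarray(qs.levels, dtype=float) / 100.0,
            cum,
            control.support.astype(float),
        )
    pooled = tq.quantile_deadenylation_rate(qs, policy=policy)
    return {
        "rates": rates,
        "group_summary": summary,
        "correlation": corr,
        "pooled_deadenylation": pooled,
        "excluded_timepoints": list(policy.deadenylation_exclude_times),
    }
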