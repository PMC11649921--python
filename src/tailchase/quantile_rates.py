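"""Per-transcript quantile deadenylation rates and mRNA decay rates.

The simplified estimator follows quantile tail-length trajectories over a
chase: per quantile level and consecutive timepoint pair, the exponential
coefficient is ln(L_prev / L_next) / dt; coefficients are averaged over
intervals, then over the upper levels (75-95th).  The per-adenosine
apparent deadenylation speed is that fractional coefficient times the
reference (control) quantile length, in adenosines per minute, with the
terminal-adenosine half-life 60*ln2 / speed in seconds.  mRNA decay rates
come from the same pairwise formula applied to library-normalized
abundances, with the control timepoint shifted forward by the
export-block offset when configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "DEFAULT_LEVELS",
    "UPPER_LEVELS",
    "FilterPolicy",
    "QuantileSeries",
    "DeadenylationRate",
    "DecayRate",
    "TranscriptRates",
    "compute_quantiles",
    "quantile_deadenylation_rate",
    "decay_rate",
    "transcript_rate_table",
    "group_summary",
]

DEFAULT_LEVELS: tuple[float, ...] = (5, 10, 15, 50, 75, 80, 85, 90, 95)
UPPER_LEVELS: tuple[float, ...] = (75, 80, 85, 90, 95)


@dataclass
class FilterPolicy:
    """Filtering rules for quantile and decay rate estimation."""

    min_reads: int = 10
    drop_above_reference: bool = True
    control_time_shift_min: float = 0.0
    down_regulated_only: frozenset[str] | None = None
    # timepoints excluded from deadenylation modeling (sample-level QC:
    # profiles carrying a new-synthesis/bimodal component are not usable
    # for quantile erosion); decay fitting keeps all timepoints
    deadenylation_exclude_times: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


@dataclass
class QuantileSeries:
    """Quantile tail lengths per (level, timepoint) for one transcript.

    ``values`` has one row per timepoint and one column per level; rows
    where n_reads < min_reads hold NaN for every level.
    """

    label: str
    timepoints: np.ndarray
    levels: np.ndarray
    values: np.ndarray
    n_reads: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.sort(np.asarray(self.levels, dtype=float))


def compute_quantiles(
    lengths_by_time: Sequence[np.ndarray],
    timepoints: Sequence[float],
    levels: Sequence[float] = DEFAULT_LEVELS,
    policy: FilterPolicy | None = None,
    label: str = "",
) -> QuantileSeries:
    """Empirical tail-length quantiles per timepoint.

    Uses the linear-interpolation quantile estimator.  All levels of a
    timepoint are absent (NaN) when that timepoint has fewer than
    ``policy.min_reads`` reads — absence, not an error, is the contract.
    """
    policy = policy or FilterPolicy()
    levels = np.sort(np.asarray(levels, dtype=float))
    if np.any(levels <= 0) or np.any(levels >= 100):
        raise ValueError("quantile levels must lie strictly inside (0, 100)")
    values = np.full((len(timepoints), len(levels)), np.nan)
    n_reads = np.zeros(len(timepoints), dtype=int)
    for j, lengths in enumerate(lengths_by_time):
        lengths = np.asarray(lengths, dtype=float)
        n_reads[j] = lengths.size
        if lengths.size >= policy.min_reads:
            values[j] = np.quantile(lengths, levels / 100.0, method="linear")
    return QuantileSeries(
        label=label,
        timepoints=np.asarray(timepoints, dtype=float),
        levels=levels,
        values=values,
        n_reads=n_reads,
    )


def _pairwise_coeffs(
    t: np.ndarray, y: np.ndarray, reference: float, drop_above_reference: bool
) -> np.ndarray:
    """ln(y_prev/y_next)/dt over consecutive usable timepoints.

    A timepoint is unusable when missing, non-positive, or (when filtering)
    above the reference value.  Unusable values are removed from the series
    before pairing, so the surviving neighbors of a removed timepoint form
    one interval spanning the gap; removed values are never imputed.
    """
    usable = np.isfinite(y) & (y > 0)
    if drop_above_reference and np.isfinite(reference):
        usable &= y <= reference + 1e-9
    idx = np.flatnonzero(usable)
    out = [
        np.log(y[a] / y[b]) / (t[b] - t[a])
        for a, b in zip(idx[:-1], idx[1:])
    ]
    return np.asarray(out, dtype=float)


@dataclass
class DeadenylationRate:
    """Upper-quantile deadenylation estimate for one transcript."""

    label: str
    coeff_per_min: float  # fractional exponential coefficient, 1/min
    rate_a_per_min: float  # per-adenosine apparent speed, adenosines/min
    terminal_adenosine_half_life_s: float
    per_level_coeff: dict[float, float]
    per_level_half_life_s: dict[float, float]
    n_intervals: int
    flags: list[str] = field(default_factory=list)


def quantile_deadenylation_rate(
    series: QuantileSeries,
    upper_levels: Sequence[float] = UPPER_LEVELS,
    policy: FilterPolicy | None = None,
) -> DeadenylationRate:
    """Average upper-quantile exponential coefficients into one rate.

    Per level: pairwise coefficients ln(L_prev/L_next)/dt over consecutive
    usable timepoints, after dropping values above the reference (the
    first timepoint, normally the control); the level coefficient is their
    mean.  The transcript coefficient is the mean over upper levels; the
    per-adenosine speed scales it by the reference quantile length, and the
    terminal-adenosine half-life is 60*ln2 divided by that speed.
    Negative coefficients that survive filtering are kept, not clamped.
    """
    policy = policy or FilterPolicy()
    t = series.timepoints
    excluded = np.zeros(len(t), dtype=bool)
    for bad_t in policy.deadenylation_exclude_times:
        excluded |= np.isclose(t, bad_t)
    per_level_coeff: dict[float, float] = {}
    per_level_hl: dict[float, float] = {}
    refs: dict[float, float] = {}
    n_int = 0
    for lvl in upper_levels:
        sel = np.flatnonzero(np.isclose(series.levels, lvl))
        if sel.size == 0:
            continue
        y = np.where(excluded, np.nan, series.values[:, sel[0]])
        usable = np.isfinite(y)
        ref = y[np.argmax(usable)] if usable.any() else float("nan")
        coeffs = _pairwise_coeffs(t, y, ref, policy.drop_above_reference)
        if coeffs.size == 0:
            continue
        c = float(coeffs.mean())
        per_level_coeff[float(lvl)] = c
        refs[float(lvl)] = float(ref)
        per_level_hl[float(lvl)] = (
            60.0 * np.log(2) / (c * ref) if c > 0 and np.isfinite(ref) else float("inf")
        )
        n_int += coeffs.size
    flags: list[str] = []
    if not per_level_coeff:
        flags.append("no_usable_intervals")
        return DeadenylationRate(
            series.label, float("nan"), float("nan"), float("nan"), {}, {}, 0, flags
        )
    coeff = float(np.mean(list(per_level_coeff.values())))
    ref_mean = float(np.mean(list(refs.values())))
    rate = coeff * ref_mean
    if coeff <= 0:
        flags.append("non_positive_rate")
        hl = float("inf")
    else:
        hl = 60.0 * np.log(2) / rate
    return DeadenylationRate(
        series.label, coeff, rate, hl, per_level_coeff, per_level_hl, n_int, flags
    )


@dataclass
class DecayRate:
    """Exponential mRNA decay estimate for one transcript."""

    label: str
    decay_coeff_per_min: float
    mrna_half_life_min: float
    n_intervals: int
    flags: list[str] = field(default_factory=list)


def decay_rate(
    timepoints: Sequence[float],
    abundances: Sequence[float],
    policy: FilterPolicy | None = None,
    label: str = "",
) -> DecayRate:
    """Pairwise exponential decay rate of normalized abundances.

    The first timepoint is the control/reference; its effective time is
    shifted forward by ``policy.control_time_shift_min`` (export-block
    chases: the pool has already been decaying for that long when the
    nominal chase starts).  Rises above the reference are dropped before
    pairing; half-life = ln2 / coefficient in minutes.
    """
    policy = policy or FilterPolicy()
    t = np.asarray(timepoints, dtype=float).copy()
    y = np.asarray(abundances, dtype=float)
    if len(t) != len(y):
        raise ValueError("timepoints and abundances must align")
    if policy.control_time_shift_min:
        # the control predates the nominal chase start by the export-block
        # establishment time, lengthening the first interval
        t[0] -= policy.control_time_shift_min
    coeffs = _pairwise_coeffs(t, y, y[0], policy.drop_above_reference)
    flags: list[str] = []
    if coeffs.size == 0:
        flags.append("no_usable_intervals")
        return DecayRate(label, float("nan"), float("nan"), 0, flags)
    c = float(coeffs.mean())
    if c <= 0:
        flags.append("non_positive_rate")
        hl = float("inf")
    else:
        hl = float(np.log(2) / c)
    return DecayRate(label, c, hl, int(coeffs.size), flags)


@dataclass
class TranscriptRates:
    transcript_id: str
    deadenylation_coeff: float  # adenosines/min (per-adenosine apparent speed)
    deadenylation_coeff_fraction: float  # fractional coefficient, 1/min
    terminal_adenosine_half_life_s: float
    decay_coeff: float  # 1/min
    mrna_half_life_min: float
    n_reads_control: int
    n_replicates: int
    flags: list[str] = field(default_factory=list)


def transcript_rate_table(
    replicates: Sequence[Mapping[str, object]],
    policy: FilterPolicy | None = None,
) -> pd.DataFrame:
    """Per-transcript rates averaged over replicates ("mean_mean").

    Each replicate is a mapping transcript_id -> dict with keys
    ``timepoints``, ``lengths_by_time`` (list of per-timepoint tail-length
    arrays) and ``abundances`` (normalized levels per timepoint).  Rates
    are computed independently per replicate, then averaged over the
    replicates where they are finite.  When the policy carries a
    down-regulated list, transcripts outside it are excluded.  Rows are
    sorted by transcript_id; unprocessable transcripts appear with flags.
    """
    policy = policy or FilterPolicy()
    all_ids: set[str] = set()
    for rep in replicates:
        all_ids |= set(rep)
    if policy.down_regulated_only is not None:
        all_ids &= set(policy.down_regulated_only)
    rows = []
    for tid in sorted(all_ids):
        dea, deaf, hl, dec, mhl = [], [], [], [], []
        n_ctrl, n_rep = 0, 0
        flags: set[str] = set()
        for rep in replicates:
            entry = rep.get(tid)
            if entry is None:
                continue
            n_rep += 1
            qs = compute_quantiles(
                entry["lengths_by_time"],
                entry["timepoints"],
                policy=policy,
                label=tid,
            )
            n_ctrl = max(n_ctrl, int(qs.n_reads[0]))
            dr = quantile_deadenylation_rate(qs, policy=policy)
            flags.update(dr.flags)
            if np.isfinite(dr.rate_a_per_min):
                dea.append(dr.rate_a_per_min)
                deaf.append(dr.coeff_per_min)
                hl.append(dr.terminal_adenosine_half_life_s)
            ab = entry.get("abundances")
            if ab is not None:
                dc = decay_rate(entry["timepoints"], ab, policy=policy, label=tid)
                flags.update(dc.flags)
                if np.isfinite(dc.decay_coeff_per_min):
                    dec.append(dc.decay_coeff_per_min)
                    mhl.append(dc.mrna_half_life_min)
        if n_rep < len(replicates):
            flags.add("low_replicate_support")
        rows.append(
            {
                "transcript_id": tid,
                "deadenylation_coeff": float(np.mean(dea)) if dea else float("nan"),
                "deadenylation_coeff_fraction": float(np.mean(deaf)) if deaf else float("nan"),
                "terminal_adenosine_half_life_s": float(np.mean(hl)) if hl else float("nan"),
                "decay_coeff": float(np.mean(dec)) if dec else float("nan"),
                "mrna_half_life_min": float(np.mean(mhl)) if mhl else float("nan"),
                "n_reads_control": n_ctrl,
                "n_replicates": n_rep,
                "flags": ";".join(sorted(flags)),
            }
        )
    return pd.DataFrame(rows)


def group_summary(
    rates: pd.DataFrame,
    groups: Mapping[str, Iterable[str]] | None = None,
    rate_columns: tuple[str, str] = ("deadenylation_coeff", "decay_coeff"),
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-group median rates and the rank correlation between rate columns.

    Returns (per-group medians, {"spearman_rho", "p_value", "n"}) computed
    over transcripts where both rate columns are finite.  Empty groups are
    skipped; single-member groups are flagged.
    """
    groups = groups or {"all": rates["transcript_id"].tolist()}
    rows = []
    for name, members in groups.items():
        sub = rates[rates["transcript_id"].isin(set(members))]
        if sub.empty:
            continue
        row = {"group": name, "n": len(sub), "flag": "single_member" if len(sub) == 1 else ""}
        for col in (
            "deadenylation_coeff",
            "terminal_adenosine_half_life_s",
            "decay_coeff",
            "mrna_half_life_min",
        ):
            row[f"median_{col}"] = float(sub[col].median())
        rows.append(row)
    a, b = rate_columns
    ok = rates[a].notna() & rates[b].notna() & np.isfinite(rates[a]) & np.isfinite(rates[b])
    if ok.sum() >= 3:
        res = spearmanr(rates.loc[ok, a], rates.loc[ok, b])
        corr = {
            "spearman_rho": float(res.statistic),
            "p_value": float(res.pvalue),
            "n": int(ok.sum()),
        }
    else:
        corr = {"spearman_rho": float("nan"), "p_value": float("nan"), "n": int(ok.sum())}
    return pd.DataFrame(rows), corr
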