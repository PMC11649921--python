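"""Ground-truth synthetic DRS chase generator.

Produces read-level poly(A)-tail tables with the statistical structure the
estimators assume: a heavy-tailed transcript abundance distribution,
per-transcript modified gamma tail profiles, a new-synthesis (40-60 A)
component in control samples only, exponential transcript decay, and
multiplicative tail-measurement noise.  Two chase mechanisms are provided:

``surface`` (default)
    Snapshots are modified gamma densities whose parameters drift linearly
    in time with the mode held fixed (shape/rate ratio constant).  The
    drift slope is calibrated per transcript so the mean upper-quantile
    (75-95th) tail length erodes at the transcript's apparent rate
    k*(1-e^(-gamma_rate)) over the chase horizon, and a pA+ recovery
    series is anchored so the absolute level at tail position 60 decays at
    the instantaneous apparent rate.  This is the mechanism that matches
    what population-level profile fits actually observe (falling quantiles
    with a rising fitted gamma_rate over chase time); see docs/methods.md
    for why verbatim protected Poisson evolution cannot reproduce falling
    normalized quantiles on a geometric-armed profile.

``kinetic``
    Verbatim protected Poisson-convolution evolution of the control
    profile (alpha = k*t with the tanh protection prefactor), the
    functional form used by the kinetics engine itself; used for oracle
    and self-consistency tests and for the near-delta "burst" regime.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import TailTable
from .kinetics import analytic_evolve
from .modgamma import DEFAULT_BETA, DEFAULT_SUPPORT_MAX, ModGammaParams, density_array

__all__ = [
    "TruthSpec",
    "SyntheticChase",
    "gen_transcriptome",
    "gen_chase",
    "write_chase",
    "preset",
    "PRESETS",
]

UPPER_QUANTILES = np.array([0.75, 0.80, 0.85, 0.90, 0.95])
MAX_SEED = 2**31 - 1


@dataclass
class TruthSpec:
    """Generator configuration; defaults define the study conditions.

    Per-transcript parameters are drawn once (per seed) and shared across
    replicates; read sampling and measurement noise differ per replicate.
    """

    n_transcripts: int = 50
    mean_reads_per_transcript: int = 2000
    timepoints: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 6.0, 8.0)
    n_replicates: int = 3
    # abundance: log-normal weights; optional (top_n, fraction) share rescaling
    abundance_log_sd: float = 1.5
    top_share: tuple[int, float] | None = None
    # tail profile at t=0
    gamma_shape_range: tuple[float, float] = (3.5, 4.0)
    gamma_rate_median: float = 0.1
    gamma_rate_log_sd: float = 0.15
    # microscopic deadenylation rate k (A/min): global, or per-transcript
    # log-normal around k when k_log_sd > 0
    k: float = 10.9
    k_log_sd: float = 0.0
    # transcript decay: log-normal lambda (1/min) rank-correlated with the
    # apparent deadenylation rate via a Gaussian copula
    lambda_median: float = float(np.log(2) / 9.7)
    lambda_log_sd: float = 0.5
    lambda_k_rank_corr: float = 0.7
    # new-synthesis component (control samples only)
    new_synthesis_fraction: float = 0.15
    new_synthesis_mode: float = 50.0
    new_synthesis_log2_sd: float = 0.35
    # measurement noise: multiplicative log-normal on read tail lengths
    noise_cv: float = 0.10
    # QC tags: fraction of reads emitted with non-PASS tags
    non_pass_fraction: float = 0.05
    mode: str = "surface"
    burst_length: float | None = None  # near-delta initial profile when set
    support_max: int = DEFAULT_SUPPORT_MAX
    beta: float = DEFAULT_BETA
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("n_transcripts", self.n_transcripts >= 1),
            ("mean_reads_per_transcript", self.mean_reads_per_transcript >= 1),
            ("timepoints", len(self.timepoints) >= 1 and self.timepoints[0] == 0.0
             and all(b > a for a, b in zip(self.timepoints, self.timepoints[1:]))),
            ("n_replicates", self.n_replicates >= 1),
            ("gamma_rate_median", self.gamma_rate_median > 0),
            ("k", self.k > 0),
            ("lambda_median", self.lambda_median > 0),
            ("new_synthesis_fraction", 0.0 <= self.new_synthesis_fraction < 1.0),
            ("noise_cv", self.noise_cv >= 0),
            ("non_pass_fraction", 0.0 <= self.non_pass_fraction < 1.0),
            ("mode", self.mode in ("surface", "kinetic")),
            ("lambda_k_rank_corr", -1.0 < self.lambda_k_rank_corr < 1.0),
            ("seed", 0 <= self.seed <= MAX_SEED),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid TruthSpec field: {name}")


@dataclass
class Transcriptome:
    """Per-transcript ground truth drawn from a TruthSpec."""

    ids: list[str]
    weights: np.ndarray  # abundance fractions, sum 1
    gamma_shape: np.ndarray
    gamma_rate: np.ndarray
    k: np.ndarray  # microscopic rate per transcript, A/min
    lam: np.ndarray  # decay constant per transcript, 1/min

    @property
    def k_app(self) -> np.ndarray:
        return self.k * (1.0 - np.exp(-self.gamma_rate))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "transcript_id": self.ids,
                "weight": self.weights,
                "gamma_shape": self.gamma_shape,
                "gamma_rate": self.gamma_rate,
                "k": self.k,
                "k_app": self.k_app,
                "lambda": self.lam,
            }
        )


@dataclass
class SyntheticChase:
    """A generated chase: read tables, abundances, recovery, and the truth."""

    spec: TruthSpec
    truth: Transcriptome
    timepoints: np.ndarray
    # tables[replicate][timepoint_index] -> TailTable
    tables: list[list[TailTable]]
    # abundance[replicate] -> DataFrame(transcript_id, raw count) per timepoint column
    abundance: list[pd.DataFrame]
    recovery_coeff: np.ndarray  # model pA+ recovery per timepoint (control = 1)


def _quantile_of_density(d: np.ndarray, q: np.ndarray | float) -> np.ndarray | float:
    c = np.cumsum(d)
    return np.interp(q, c / c[-1], np.arange(len(d), dtype=float))


def _main_density(spec: TruthSpec, shape: float, rate: float) -> np.ndarray:
    if spec.burst_length is not None:
        d = np.zeros(spec.support_max + 1)
        center = int(round(spec.burst_length))
        d[center] = 0.995
        for off in (-1, 1):
            if 0 < center + off <= spec.support_max:
                d[center + off] += 0.0025
        return d / d.sum()
    params = ModGammaParams(shape, rate, beta=spec.beta, support_max=spec.support_max)
    return density_array(params)


def _new_synthesis_density(spec: TruthSpec) -> np.ndarray:
    # deposited tails are bounded: poly(A) polymerase adds a canonical
    # length, so the log-normal shape is truncated two log-sds above the
    # mode (an unbounded upper tail would imply freshly made 100+ A tails,
    # which the 40-60 A new-synthesis component rules out)
    i = np.arange(spec.support_max + 1, dtype=float)
    mu = np.log2(spec.new_synthesis_mode)
    with np.errstate(divide="ignore"):
        z = (np.log2(np.where(i < 1, 1.0, i)) - mu) / spec.new_synthesis_log2_sd
    d = np.where((i < 1) | (z > 2.0), 0.0, np.exp(-0.5 * z**2))
    return d / d.sum()


def gen_transcriptome(spec: TruthSpec, rng: np.random.Generator | None = None) -> Transcriptome:
    """Draw per-transcript ground-truth parameters."""
    spec.validate()
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_transcripts
    ids = [f"TX{g:04d}" for g in range(n)]
    w = np.exp(rng.normal(0.0, spec.abundance_log_sd, n))
    w = w / w.sum()
    if spec.top_share is not None:
        top_n, frac = spec.top_share
        if not 0 < top_n < n or not 0 < frac < 1:
            raise ValueError("invalid TruthSpec field: top_share")
        order = np.argsort(w)[::-1]
        top = order[:top_n]
        rest = order[top_n:]
        w[top] *= frac / w[top].sum()
        w[rest] *= (1.0 - frac) / w[rest].sum()
    shape = rng.uniform(*spec.gamma_shape_range, n)
    # Gaussian copula between the apparent-rate driver and lambda; the
    # Pearson rho on the normal scale is chosen so the Spearman rho of the
    # margins equals the requested rank correlation
    rho_s = spec.lambda_k_rank_corr
    rho_z = 2.0 * np.sin(np.pi * rho_s / 6.0)
    z1 = rng.normal(0.0, 1.0, n)
    z2 = rho_z * z1 + np.sqrt(1.0 - rho_z**2) * rng.normal(0.0, 1.0, n)
    rate = spec.gamma_rate_median * np.exp(spec.gamma_rate_log_sd * z1)
    if spec.k_log_sd > 0:
        # per-transcript k varies: it is the apparent-rate driver, so it
        # takes the copula coordinate and gamma_rate decouples
        k = spec.k * np.exp(spec.k_log_sd * z1)
        rate = spec.gamma_rate_median * np.exp(
            spec.gamma_rate_log_sd * rng.normal(0.0, 1.0, n)
        )
    else:
        k = np.full(n, spec.k)
    lam = spec.lambda_median * np.exp(spec.lambda_log_sd * z2)
    return Transcriptome(ids, w, shape, rate, k, lam)


def _surface_drift_slope(
    spec: TruthSpec,
    d_main0: np.ndarray,
    rate0: float,
    k_app: float,
    horizon: float,
) -> float:
    """Calibrate the gamma_rate drift slope for one transcript.

    Beyond the (fixed) mode, the upper quantile of the profile sits at
    mode + Z/gamma_rate; the slope is chosen so the mean upper quantile of
    the pre-existing (main) profile erodes by k_app per minute over the
    horizon.  A soft floor keeps the target denominator positive (and the
    slope monotone in k) for transcripts fast enough to exhaust the arm.
    """
    mode = float(np.argmax(d_main0))
    L_main = float(np.mean(_quantile_of_density(d_main0, UPPER_QUANTILES)))
    z0 = rate0 * (L_main - mode)
    denom = L_main - k_app * horizon - mode
    floor = 0.3 * (L_main - mode)
    if denom < floor:
        denom = floor**2 / (2.0 * floor - denom)
    return (z0 / denom - rate0) / horizon


def _surface_state(
    spec: TruthSpec,
    shape0: float,
    rate0: float,
    k: float,
    r1: float,
    d_main0: np.ndarray,
    t: float,
) -> tuple[np.ndarray, float]:
    """(main tail density, pA+ recovery) for one transcript at chase time t."""
    rate_t = rate0 + r1 * t
    shape_t = shape0 * rate_t / rate0  # mode invariance: shape/rate constant
    d_t = _main_density(spec, shape_t, rate_t)
    # recovery anchored so the absolute level at position 60 decays at the
    # instantaneous apparent rate: integral of k*(1-e^(-rate(u))) du
    if abs(r1) > 1e-12:
        integral = k * t - k * np.exp(-rate0) * (1.0 - np.exp(-r1 * t)) / r1
    else:
        integral = k * (1.0 - np.exp(-rate0)) * t
    anchor = 60 if spec.support_max >= 60 else spec.support_max // 2
    recovery = float(np.exp(-integral) * d_main0[anchor] / d_t[anchor])
    return d_t, min(recovery, 1.0)


def gen_chase(spec: TruthSpec, truth: Transcriptome | None = None) -> SyntheticChase:
    """Generate a full chase: reads, abundances, recovery coefficients.

    All randomness flows from ``spec.seed``; identical specs yield
    byte-identical datasets.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if truth is None:
        truth = gen_transcriptome(spec, rng)
    n = spec.n_transcripts
    t_grid = np.asarray(spec.timepoints, dtype=float)
    horizon = float(t_grid.max()) if t_grid.max() > 0 else 1.0
    d_new = _new_synthesis_density(spec)

    # per-transcript control densities and (surface mode) drift slopes
    d0 = np.array(
        [_main_density(spec, truth.gamma_shape[g], truth.gamma_rate[g]) for g in range(n)]
    )
    k_app = truth.k_app
    if spec.mode == "surface":
        r1 = np.array(
            [
                _surface_drift_slope(spec, d0[g], truth.gamma_rate[g], k_app[g], horizon)
                for g in range(n)
            ]
        )

    # model densities and per-transcript recovery at each timepoint.
    # New synthesis appears only in the control: the freshly made cohort
    # is nuclear at the moment export is blocked, so it never joins the
    # cytoplasmic chase pool — depletion timepoints evolve the control
    # profile minus its new-synthesis component, and the recovery (mass
    # ratio against the full control) carries the (1 - fraction) factor.
    f_new = spec.new_synthesis_fraction
    dens = np.empty((len(t_grid), n, spec.support_max + 1))
    rec_g = np.empty((len(t_grid), n))
    for j, t in enumerate(t_grid):
        for g in range(n):
            if t == 0.0:
                d_main, r_main = d0[g], 1.0
            elif spec.mode == "surface":
                d_main, r_main = _surface_state(
                    spec, truth.gamma_shape[g], truth.gamma_rate[g],
                    truth.k[g], r1[g], d0[g], t,
                )
            else:
                x = analytic_evolve(d0[g], truth.k[g] * t, protected=True, beta=spec.beta)
                r_main = float(x.sum())
                d_main = x / r_main if r_main > 0 else np.zeros_like(x)
            if f_new > 0 and t == 0.0:
                dens[j, g] = (1.0 - f_new) * d_main + f_new * d_new
                rec_g[j, g] = 1.0
            else:
                dens[j, g] = d_main
                rec_g[j, g] = (1.0 - f_new) * r_main if f_new > 0 else r_main
    recovery = (truth.weights[None, :] * rec_g).sum(axis=1) / truth.weights.sum()

    non_pass_tags = np.array(["FAIL", "SUFFCLIP", "ADAPTER", "NOREGION"])
    support = np.arange(spec.support_max + 1, dtype=float)
    sigma = float(np.sqrt(np.log(1.0 + spec.noise_cv**2))) if spec.noise_cv > 0 else 0.0
    total0 = spec.mean_reads_per_transcript * n

    tables: list[list[TailTable]] = []
    abundance: list[pd.DataFrame] = []
    counter = 0
    for rep in range(spec.n_replicates):
        rep_tables: list[TailTable] = []
        counts_by_time: dict[str, np.ndarray] = {}
        for j, t in enumerate(t_grid):
            surv = truth.weights * np.exp(-truth.lam * t)
            n_reads = int(rng.poisson(total0 * surv.sum()))
            counts = rng.multinomial(n_reads, surv / surv.sum())
            counts_by_time[f"t{t:g}"] = counts
            tids, lengths = [], []
            for g in range(n):
                if counts[g] == 0:
                    continue
                raw = rng.choice(support, size=counts[g], p=dens[j, g])
                if sigma > 0:
                    raw = raw * np.exp(rng.normal(-0.5 * sigma**2, sigma, counts[g]))
                tids.extend([truth.ids[g]] * counts[g])
                lengths.append(np.clip(raw, 0.0, spec.support_max))
            lengths_arr = np.concatenate(lengths) if lengths else np.empty(0)
            qc = np.full(len(tids), "PASS", dtype=object)
            if spec.non_pass_fraction > 0 and len(tids):
                flip = rng.random(len(tids)) < spec.non_pass_fraction
                qc[flip] = rng.choice(non_pass_tags, size=int(flip.sum()))
            records = pd.DataFrame(
                {
                    "read_id": [f"read{counter + m:08d}" for m in range(len(tids))],
                    "transcript_id": tids,
                    "tail_length": lengths_arr,
                    "qc_tag": qc,
                }
            )
            counter += len(tids)
            rep_tables.append(
                TailTable(records, sample_id=f"rep{rep + 1}_t{t:g}", time_min=float(t))
            )
        tables.append(rep_tables)
        ab = pd.DataFrame(counts_by_time, index=truth.ids)
        ab.index.name = "transcript_id"
        abundance.append(ab)
    return SyntheticChase(spec, truth, t_grid, tables, abundance, recovery)


def write_chase(chase: SyntheticChase, out_dir: str | Path) -> list[Path]:
    """Write a chase as nanopolish-polya-dialect TSVs plus manifest files.

    Layout: one read table per (replicate, timepoint), one abundance table
    per replicate, ``recovery.tsv``, ``truth.tsv`` (per-transcript ground
    truth) and ``manifest.json`` (design + spec + seed).  Reads written
    here round-trip through ``read_polya_table`` without loss.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for rep, rep_tables in enumerate(chase.tables):
        for table in rep_tables:
            p = out / f"{table.sample_id}.tsv"
            df = table.records.rename(
                columns={
                    "read_id": "readname",
                    "transcript_id": "contig",
                    "tail_length": "polya_length",
                }
            )[["readname", "contig", "polya_length", "qc_tag"]]
            df.to_csv(p, sep="\t", index=False)
            written.append(p)
        p = out / f"abundance_rep{rep + 1}.tsv"
        chase.abundance[rep].to_csv(p, sep="\t")
        written.append(p)
    p = out / "recovery.tsv"
    pd.DataFrame(
        {"time_min": chase.timepoints, "recovery_coeff": chase.recovery_coeff}
    ).to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "truth.tsv"
    chase.truth.to_frame().to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "manifest.json"
    manifest = {
        "spec": asdict(chase.spec),
        "timepoints": list(map(float, chase.timepoints)),
        "n_replicates": chase.spec.n_replicates,
        "seed": chase.spec.seed,
    }
    p.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    written.append(p)
    return written


def preset(name: str, seed: int = 0, **overrides: object) -> TruthSpec:
    """Named study-condition presets for the generator."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return TruthSpec(seed=seed, **kwargs)  # type: ignore[arg-type]


PRESETS: dict[str, dict[str, object]] = {
    # global-rate export-block chase: k = 10.9 A/min, gamma_rate ~ 0.1;
    # transcript decay varies but is not tied to deadenylation (the
    # deadenylation rate is global here, so there is no per-transcript
    # rate structure to correlate with)
    "mex67_chase": {"lambda_k_rank_corr": 0.0},
    # per-transcript rate panel: k varies across transcripts and decay is
    # rank-correlated with it; read depth matches the default preset's
    # per-transcript scale, and the k spread is set wide relative to the
    # per-transcript estimator error so that rank-correlation recovery is
    # attenuation-limited by design, not by sampling noise
    "transcript_panel": {
        "n_transcripts": 200,
        "mean_reads_per_transcript": 2000,
        "k_log_sd": 0.5,
        "gamma_rate_log_sd": 0.0,
    },
    # near-delta initial profile evolved by the verbatim kinetic mechanism
    "burst": {
        "n_transcripts": 1,
        "mean_reads_per_transcript": 5000,
        "burst_length": 60.0,
        "mode": "kinetic",
        "noise_cv": 0.0,
        "new_synthesis_fraction": 0.0,
        "non_pass_fraction": 0.0,
        "abundance_log_sd": 0.0,
    },
}
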