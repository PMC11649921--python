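# Methods

This document specifies the model, the estimators, the synthetic-data
generator, the numerical choices, and the known limitations of
`tailchase`.

## 1. The modified gamma tail-length distribution

Tail lengths are binned to integers `i = 0..250` adenosines. The
steady-state profile is

    p(i) ∝ tanh(β·i)^γ_shape · exp(−γ_rate·i),   p(0) = 0,

normalized over the support. `tanh(β·i)` is the probability that a tail
of length `i` is bound (protected) by poly(A)-binding protein;
β = 0.096/A is fixed, giving tanh(0.096·20) = 0.96 — protection
saturates over a single ~20 A protein footprint. Two regimes follow:

- **Left arm (i ≲ 20):** protection shapes the density; `γ_shape`
  controls how steeply short tails are depleted.
- **Right arm (i ≳ 40):** tanh ≈ 1 and the density is geometric with
  adjacent-bin ratio `e^(−γ_rate)`.

As β → 0 the density tends to the classical gamma law with mean
`(γ_shape + 1)/γ_rate`; at operating β the mean is lower because the
protection factor has already saturated.

`fit_modgamma` fits (γ_shape, γ_rate) to a histogram by bounded
least squares on the density; `distribution_stats` returns
mean/variance/median of a fitted law. `right_arm_rate` estimates
γ_rate alone as the negative slope of the log density over a window
(default 40–80 A) — unlike the whole-profile fit it is insensitive to
peak-region broadening when the sample aggregates transcripts with
different `γ_shape`.

### New-synthesis residual

Control (pre-chase) samples contain a freshly made cohort with tails
deposited at a canonical length: a log-normal bump (mode ≈ 50 A,
log2-sd ≈ 0.35, truncated two sds above the mode). `new_synthesis_residual`
fits this component on top of the modified-gamma baseline and reports
its mass fraction. With `refit_baseline=True` the baseline is first
re-estimated by `masked_baseline`: an amplitude-free modified-gamma
refit that iteratively masks outlier bins (residual > 2.5 robust sds),
so the bump cannot be absorbed into the baseline on heterogeneous
aggregates. The bump's mode is then constrained to the 40–60 A
deposition band.

## 2. Deadenylation kinetics

### Evolution operators

Each tail loses adenosines independently as a Poisson process. Writing
`α = k·t` for the expected number of removals after time `t` at
microscopic rate `k` (A/min), the absolute level of bin `i` evolves as
the Poisson-kernel sum

    n(i, α) = Σ_{j≥i} n0(j) · e^(−α) α^(j−i)/(j−i)!      (analytic_evolve)

optionally multiplied by `tanh(β·i)^α` to model the accelerated loss of
poorly protected short tails (`protected=True`; a fixed
`protection_exponent` may replace α). Bin 0 is an absorbing sink.
`ode_evolve` integrates the equivalent coupled ODE system
`dx_i/dt = k·(x_{i+1} − x_i)` with DOP853 at rtol 1e-12 and serves as
the brute-force oracle; the two agree to better than 1e-8 per bin.

A key consequence of the model: on the saturated right arm the profile
is quasi-stationary, `n(i, α) ≈ n0(i)·e^(−γ_rate·α)`. The *shape* of the
distribution barely changes during the chase; the kinetic signal lives
in the *absolute level* of the window, which decays at
`R_app = k·(1−e^(−γ_rate))` per minute.

### Decay adjustment and position half-lives

Sequencing depth tracks input material, so raw densities are rescaled to
absolute levels by per-timepoint recovery coefficients
(`adjust_for_decay`). `position_half_lives` fits an exponential to each
tail position in the window (default 40–80 A), bootstraps the
window-mean half-life, and reports it in seconds.

### Apparent → microscopic conversion

`apparent_to_microscopic(R_app, γ_rate)` inverts

    R_app = k·(1 − e^(−γ_rate)),

returning `k = R_app/(1 − e^(−γ_rate))`; with `small_gamma_approx=True`
the denominator is γ_rate itself (the 1−e^(−γ) ≈ γ form). At
R_app = 1.09 A/min and γ_rate = 0.1 these give 10.9 and 11.45 A/min.
The companion half-life is `60·ln2/R_app` seconds (38 s at 1.09 A/min).

### Virtual-deadenylation (α) matching

As an independent route, each depletion timepoint's absolute profile is
matched against the control profile evolved by a grid of α values;
the best α per timepoint, regressed through the origin against time,
estimates `k` directly. Details that matter:

- The seed is the control's outlier-masked modified-gamma baseline
  (its new-synthesis component is nuclear at the moment of the export
  block and never joins the chase pool), and recovery coefficients are
  rescaled by `1/(1 − fraction_new)` accordingly.
- Matching is log-least-squares on absolute levels over the half-life
  window (`metric="log_lsq"`, `window=(40, 80)`): log-space comparison
  pivots at the window center, so a small mismatch between the seed's
  arm slope and the observed one does not bias the amplitude match.
- γ_rate drifts upward over a chase (short-tailed messages die first),
  so the raw α at time t reflects `k·∫γ(τ)dτ / γ_0`; each α is rescaled
  by `γ_0 / γ̄(0..t)` (trapezoidal running mean of the measured per-time
  right-arm slopes) before the slope fit.

### Control time shift

In export-block designs the control sample predates the nominal chase
start. `estimate_time_shift` fits per-position exponentials to the
depletion series and finds the forward shift `s` that places the control
on the extrapolated trend (`s > 0` means the control is fresher than the
t = 0 trend by `s` minutes); a shift at the search-grid boundary is
flagged as unreliable. The shift lengthens the first decay interval via
`FilterPolicy.control_time_shift_min`.

## 3. Quantile deadenylation and decay rates

Per transcript and timepoint, tail-length quantiles are computed at
levels 5–95 (linear-interpolation estimator); a timepoint with fewer
than `min_reads` (default 10) reads is absent, not an error. For each
upper level (75–95), the exponential coefficient over consecutive
*usable* timepoints is `ln(L_prev/L_next)/Δt`; unusable values
(missing, non-positive, or above the reference when
`drop_above_reference` is set) are removed first, so the surviving
neighbors bridge the gap — removed values are never imputed. The
transcript coefficient is the mean over intervals and levels; the
per-adenosine speed multiplies it by the reference quantile length, and
the terminal-adenosine half-life is `60·ln2` divided by that speed.
mRNA decay rates apply the same pairwise rule to library-normalized
abundances (normalized against the control library, not per sample,
so pool decay is preserved). Rates are computed per replicate and then
averaged; transcripts missing from replicates are flagged. The pooled
(all-transcript) estimate references the control with its new-synthesis
residual removed, since the chase erodes only the pre-existing pool.

`group_summary` reports per-group median rates and the Spearman rank
correlation between deadenylation and decay over transcripts where both
are finite.

## 4. The synthetic-data generator

`tailchase.synth` defines the study conditions; its parameters are part
of the experimental design, not tuning knobs. A `TruthSpec` fixes the
transcriptome (log-normal abundances, per-transcript γ_shape/γ_rate,
microscopic rate k — global or log-normal, decay constants λ
rank-correlated with the apparent rate via a Gaussian copula), the
chase design (timepoints, replicates), and the measurement layer
(multiplicative log-normal length noise, non-PASS QC tags, Poisson/
multinomial read sampling). New synthesis appears only in the control;
depletion timepoints evolve the control minus that component, and the
recovery coefficients carry the corresponding `(1 − fraction)` factor.
Two evolution modes exist: `kinetic` applies the protected analytic
operator verbatim; `surface` (default) evolves each transcript on a
γ-drift surface consistent with the quasi-stationary solution. All
randomness flows from `TruthSpec.seed`; identical specs yield
byte-identical run directories (read tables, abundances, recovery,
ground truth, manifest).

Presets: `mex67_chase` (global k = 10.9 A/min, 6 timepoints × 3
replicates), `transcript_panel` (200 transcripts, per-transcript k with
rank correlation 0.7 to λ), `burst` (near-delta initial profile for
mechanism tests).

Scope: the generator models a single well-mixed cytoplasmic pool with
time-homogeneous per-transcript rates. It does not model biphasic
per-transcript deadenylation, re-adenylation, partial export-block
leakage, or sequencing basecall-length bias beyond the multiplicative
noise term.

## 5. Numerics

- Density fits use `scipy.optimize.curve_fit` with explicit bounds
  (γ_shape ∈ [0, 30], γ_rate ∈ [1e-4, 1]; masked refit adds amplitude
  ∈ [0.2, 1.2]); convergence and parameter standard errors are reported.
- The ODE oracle uses DOP853 at rtol 1e-12 / atol 1e-14.
- Half-life confidence intervals are percentile bootstrap over window
  positions (default 1000 draws, seeded).
- Quantiles use numpy's linear-interpolation estimator; histogram
  binning rounds half-up and clamps to the support.
- All stochastic code paths take explicit seeds; workflows are
  deterministic given a run directory.

## 6. Limitations

- The apparent→microscopic correction assumes the quasi-stationary
  right-arm regime; it is meaningless when the window carries too little
  mass (late timepoints of a fast chase) or when γ_rate is poorly
  determined (`right_arm_rate` returns NaN on sparse windows).
- α-matching assumes the control profile (minus new synthesis) is the
  ancestor of every depletion profile; condition changes mid-chase
  violate this.
- The γ-drift correction uses a trapezoidal running mean of measured
  arm slopes; with few timepoints the early-drift portion is
  under-resolved.
- Quantile rates are apparent (position-level) speeds; they measure the
  microscopic rate only after the same `1/(1−e^(−γ))` correction.
- The rank-correlation estimate between per-transcript deadenylation
  and decay is attenuated by estimator noise in both coordinates; on
  the panel preset the attenuation is ≈ 0.88 per coordinate, so a true
  ρ = 0.7 reads out near 0.6.
- Aggregate (multi-transcript) profiles mix γ_shape values; only
  arm-window statistics, not whole-profile fits, are unbiased there.
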