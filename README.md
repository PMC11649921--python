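# tailchase

Deadenylation and mRNA decay kinetics from poly(A)-tail chase experiments
measured by nanopore direct RNA sequencing.

After transcription, the poly(A) tail of an mRNA is shortened
(deadenylated) until the message is decapped and degraded. Blocking
nuclear mRNA export freezes the supply of new transcripts, so the
cytoplasmic pool becomes a synchronized "chase": sampling tail-length
distributions over time after the block watches the whole transcriptome
slide toward shorter tails. `tailchase` turns per-read tail-length
tables from such a chase into

- fitted steady-state tail-length profiles (a modified gamma law),
- a global deadenylation rate in adenosines per minute, with the
  conversion between the *apparent* rate (what a tail-length marker
  appears to do) and the *microscopic* rate (what the exonuclease does),
- per-transcript deadenylation and decay rates from quantile
  trajectories, and their rank correlation,
- a fully parameterized synthetic-data generator for validating every
  estimator against known ground truth.

## The model in one paragraph

Steady-state tail lengths follow a modified gamma distribution
`p(i) ∝ tanh(βi)^γ_shape · e^(−γ_rate·i)` on `i = 0..250` adenosines.
The `tanh(βi)` factor (β = 0.096/A) is the probability that a tail of
length `i` is protected by poly(A)-binding protein; it saturates for
`i ≳ 20` (tanh(0.096·20) = 0.96), so the right arm of the distribution
is geometric with ratio `e^(−γ_rate)`. During a chase, each tail loses
adenosines as a Poisson process with microscopic rate `k` (A/min); the
distribution evolves by a Poisson-kernel shift plus loss of poorly
protected short tails. Because the profile is quasi-stationary, a marker
at fixed tail length decays exponentially with *apparent* rate
`R_app = k·(1−e^(−γ_rate))` — observing tail positions underestimates
the enzyme's speed by roughly a factor `1/γ_rate` when `γ_rate` is small.

## Quickstart (CLI)

```bash
# generate a synthetic chase (50 transcripts, 6 timepoints, 3 replicates)
tailchase synth --preset mex67_chase --seed 1 --out run/

# fit tail profiles per timepoint
tailchase fit-gamma --run run/ --out profiles/

# global deadenylation kinetics
tailchase kinetics --run run/ --out kinetics/

# per-transcript quantile rates
tailchase quantile-rates --run run/ --out rates/
```

Every command accepts `--config file.yaml` (flags take precedence),
`--dry-run` to print the resolved configuration, and writes a
`provenance.json` (version, subcommand, resolved config) next to its
outputs.

## Worked example

The default preset generates a chase whose true microscopic rate is
k = 10.9 A/min with γ_rate ≈ 0.1. Running the kinetics chain on it
(`analysis/01_simulate_chase.py` then `analysis/03_deadenylation_kinetics.py`)
prints, among other fields:

```
"adenosine_half_life_s": 35.1,
"apparent_rate_a_per_min": 1.185,
"gamma_rate_window_mean": 0.1036,
"microscopic_rate_a_per_min": 11.44,
"alpha_slope_a_per_min": 11.74,
"alpha_pearson_r": 0.9988
```

Reading this: tail positions in the 40–80 A window lose mass with a
~35 s half-life (apparent rate 1.19 A/min), but correcting by the
measured right-arm slope γ̂ = 0.104 recovers a microscopic rate of
11.4 A/min — within 5% of the true 10.9, and an order of magnitude
above the apparent rate. The independent virtual-deadenylation
(α-matching) route gives 11.7 A/min, agreeing with the correction route
to within 3%. The quantile estimator on the same run
(`analysis/04_transcript_rates.py`) returns a pooled per-adenosine speed
of 1.23 A/min, concordant with the apparent rate from the kinetic route
(1.19 A/min).

On the 200-transcript panel preset, where per-transcript deadenylation
and decay rates are constructed at Spearman ρ = 0.7, the estimated
rank correlation between the two per-transcript rate columns is 0.62 —
attenuated by estimator noise, as expected, and strongly significant
(p ≈ 3·10⁻²²).

As a library:

```python
import numpy as np
from tailchase import io, modgamma, kinetics

table = io.read_polya_table("rep1_t0.tsv")          # PASS reads only
dist = io.build_distribution(table)                  # 0..250 A histogram
params = modgamma.fit_modgamma(dist)                 # gamma_shape, gamma_rate
gamma_hat = modgamma.right_arm_rate(dist)            # robust arm slope
est = kinetics.apparent_to_microscopic(1.09, gamma_hat)
print(est.microscopic_rate, est.adenosine_half_life_s)
```

## Package layout

| module | contents |
| --- | --- |
| `tailchase.io` | tail-table reading, QC filtering, histograms, abundance normalization |
| `tailchase.modgamma` | modified gamma density, fitting, right-arm rate, new-synthesis residual, parameter trends |
| `tailchase.kinetics` | evolution operators (analytic + ODE oracle), decay adjustment, position half-lives, rate conversion, α-matching |
| `tailchase.quantile_rates` | per-transcript quantile deadenylation and decay rates, filters, group summaries |
| `tailchase.synth` | ground-truth synthetic chase generator and presets |
| `tailchase.workflows` | run-directory loading and the end-to-end chains |
| `tailchase.cli` | `tailchase` command group |

See `docs/methods.md` for the model, the estimators, and their
limitations.

## Testing

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, CLI round-trips, and
`tests/test_acceptance.py` with the headline-number and
property-recovery checks (oracle equivalence, parameter recovery,
rate recovery, quantile concordance, correlation recovery, filter
bookkeeping).
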