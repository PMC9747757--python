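# quasicrit

Neuronal-avalanche analysis under the quasicriticality framework: a
cortical branching model (CBM) simulator, avalanche extraction from
continuous multichannel recordings, effective critical exponents with the
γ-scaling-line "position" biomarker, and the dynamical statistics that go
with them (susceptibility, local time fluctuation, branching ratio,
avalanche-size variance). A synthetic MEG-like cohort generator makes the
entire pipeline testable end to end without any proprietary recordings.

## Who this is for

Researchers studying whether population neural dynamics (MEG/EEG/spiking)
operate near a critical branching point, and how far a subject sits along
the scaling line that organizes near-critical systems. The package covers
the full chain from raw multichannel time series (or simulated rasters) to
cohort-level statistics.

## The science in brief

Cascades of threshold events — neuronal avalanches — are characterized by
their size `S` (total events) and duration `T` (time bins). Near a critical
branching point,

    P(S) ~ S^(-τ_S),    P(T) ~ T^(-τ_T),    ⟨S⟩(T) ~ T^γ,

and the exponents obey the scaling relation `γ = (τ_T − 1)/(τ_S − 1)`.
Real neural systems are driven by spontaneous activity (`p_s > 0`), which
concatenates avalanches and shifts the *effective* exponents (τ̃_S, τ̃_T)
down a line of slope γ — the γ-scaling line. The mismatch
`|(τ̃_T−1)/(τ̃_S−1) − γ|` is the distance-to-criticality coefficient (DCC).

The CBM is a probabilistic cellular automaton on a random directed graph
(`N` nodes, `k_in` inbound edges each). Inbound edge ranks carry an
exponential weight profile `p_n ∝ e^(−B n)`; the bias `B` models how
skewed the connection strengths are (used here as an aging proxy), and the
branching parameter `κ` scales all transmission probabilities. With noise
`p_s > 0` the critical point is replaced by a quasicritical region whose
susceptibility peak (`χ = N·var(ρ₁)`, with `ρ₁(t)` the active fraction)
traces the Widom line in the (p_s, κ) plane.

## Worked example

```python
import numpy as np
from quasicrit import (CBMConfig, simulate_counts, extract_avalanches,
                       fit_exponent_pair, activity_density, susceptibility)

cfg = CBMConfig(n_nodes=256, k_in=5, kappa=1.12, p_s=1e-3, bias=0.6,
                refractory=1, n_steps=2_000_000, seed=1)
counts = simulate_counts(cfg)                 # per-step active-node counts
catalog = extract_avalanches(counts)          # avalanche (S, T) catalog
pair = fit_exponent_pair(catalog, system_size=cfg.n_nodes)
chi = susceptibility(activity_density(counts, n_nodes=cfg.n_nodes))
print(f"n_avalanches = {len(catalog)}")
print(f"tau_S = {pair.tau_S.exponent:.3f}  tau_T = {pair.tau_T.exponent:.3f}")
print(f"gamma = {pair.gamma_fit:.3f}  fraction = {pair.fraction:.3f}  chi = {chi:.3f}")
```

Output (exact values vary slightly with seed and run length):

```
n_avalanches = 5549
tau_S = 1.524  tau_T = 1.565
gamma = 1.552  fraction = 1.078  chi = 0.445
```

Read: from one flat-bias simulation near the susceptibility peak the size
exponent ≈ 1.52 and duration exponent ≈ 1.57 were fitted over the
physically scale-free window; χ ≈ 0.45 is the peak-level susceptibility at
this bias, and the scaling fraction (1.08) and independently fitted γ
(1.55) are the two sides of the scaling relation — single short runs
scatter around it, and ensemble averages (see the acceptance script) move
the pair toward the relation, as expected at the Widom line.

A full synthetic aging cohort, analyzed end to end:

```python
from quasicrit import CohortConfig, generate_cohort, run_cohort

subjects, meta = generate_cohort(CohortConfig(n_subjects=16, duration_s=60.0, seed=11))
results = run_cohort(subjects)
print(results.statistics.head(3).to_string(index=False))
```

```
statistic        x        y     value            p  n
  pearson      age position -0.898073 2.281285e-06 16
  pearson      age      chi  0.981001 1.875485e-11 16
  pearson position      chi -0.913600 7.157976e-07 16
```

Older synthetic subjects (stronger weight bias) sit lower on the
γ-scaling line and show higher susceptibility — the trend pattern the
biomarker is designed to expose.

The same functionality is exposed on the command line via `quasicrit`
(subcommands `simulate`, `sweep`, `binarize`, `avalanches`, `exponents`,
`scaling-line`, `metrics`, `make-cohort`, `run`).

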