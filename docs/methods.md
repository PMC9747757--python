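# Methods

This note documents the models, estimators and numerical choices behind
`quasicrit`, in the order data flows through the package.

## Cortical branching model

The simulator is a probabilistic cellular automaton on a directed random
graph. Each of `n_nodes` (default 256) nodes receives exactly `k_in`
(default 5) in-edges from distinct, uniformly drawn sources; wiring is
resampled (up to 1000 attempts) until the underlying undirected graph is a
single component. Inbound edges of every node are ranked `n = 1..k_in` and
carry transmission probabilities from the exponential weighting function

    p_n = exp(-B n) / sum_{m=1..k_in} exp(-B m),

so each node's inbound probabilities sum to one. `B = 0` gives homogeneous
weights; increasing `B` concentrates weight on few strong inputs — the
package's proxy for the age-related skewing of cortical connectivity. The
full edge weight is `P_ij = κ p_{n_ij}`. Because every column of the weight
matrix sums to exactly `κ`, the branching parameter is also the leading
eigenvalue of the connectivity, and with `p_s = 0` the model is an exact
Galton–Watson branching process with mean offspring `κ` in the
large-`N` limit (the basis of one of the oracle tests).

Node states: a node is quiescent, active for exactly one step, then
refractory for `refractory` steps (default 1), then quiescent again. Per
update, a node that is quiescent *after* refractory decay activates if any
in-edge from a currently active source transmits (`uniform ≤ P_ij`, edges
evaluated in ascending source index) or by a spontaneous draw
(`uniform ≤ p_s`, default 1e-3); spontaneous activation is blocked during
refractoriness. Simulations start all-quiescent and discard a burn-in of
1000 steps before statistics are collected. One seeded generator drives
each simulation; long runs proceed in 250 000-step chunks, each advancing
the seed deterministically, so a (config, seed) pair reproduces bit-for-bit.

Design choices that were genuinely open: the weighting function's
normalisation is over *inbound* edges (the alternative, outbound
normalisation, collapses the susceptibility to a fraction of its expected
peak value and was rejected on that evidence); refractory semantics are
"active 1 step, refractory τ_r steps"; spontaneous and driven activation
combine as a logical OR within one update.

Run lengths: reference-cell runs simulate until 50 000 complete avalanches
or 5×10⁶ steps, whichever comes first. The susceptibility estimate at
strong bias grows slowly with window length (activity switches between
quiet and engaged epochs on ~10⁵-step scales), so χ is always quoted
together with the run length used; ensembles of ≥4 independent runs give
the run-to-run SD.

## Avalanche definition and exponent estimation

A raster (binary units × bins) is reduced to per-bin event counts; maximal
runs of non-empty bins are avalanches with size `S` (total events) and
duration `T` (bins). Runs touching either recording edge are discarded
(their true extent is unknown).

Power-law tails are fitted by discrete maximum likelihood with the
normalising constant as a Hurwitz-zeta difference (doubly truncated when
an upper cutoff is given); the lower cutoff is selected by minimising the
Kolmogorov–Smirnov distance between the windowed sample and its fit.
`fit_power_law` with no window arguments behaves as the classic full-range
estimator (and recovers a zeta-sampled exponent of 1.6 to ±0.03 at
n = 10⁵); a log-binned least-squares alternative sits behind
`method="lsq"`.

Quasicritical avalanche distributions are *not* clean power laws: the head
(S = 1, T = 1) is dominated by isolated spontaneous activations, and the
tail carries a bump of system-spanning concatenated avalanches. Plain
full-range KS selection latches onto one or the other. The default policy
for model and subject catalogs (`fit_exponent_pair(..., system_size=N)`)
therefore fits the physically scale-free window:

* sizes on `[x_min, N]` — N co-activating units bound one clean cascade;
* durations on `[x_min, T*]`, where `T*` is the duration at which the
  fitted ⟨S⟩(T) ~ T^γ line reaches `N` (longer avalanches necessarily
  revisit units); inverting the regression line is much steadier
  run-to-run than reading the crossing off raw pointwise means;
* `x_min` KS-selected within `[2, x_max/6]`, excluding the
  spontaneous-event head and windows too narrow to constrain a slope, with
  at least 50 tail values.

γ is the OLS slope of log₁₀⟨S⟩(T) on log₁₀T over durations with ≥10
avalanches. The scaling fraction `(τ_T−1)/(τ_S−1)` carries first-order
propagated errors; DCC is its absolute difference from the fitted γ.
Exponent uncertainties are nonparametric bootstrap SDs (200 resamples,
refitting within the chosen window) or the asymptotic `(α−1)/√n` when
bootstrap is disabled.

## Activity statistics

With `ρ₁(t)` the active fraction per bin: `χ = N·var(ρ₁)` (population
variance), `LTF = sqrt(χ/N)/⟨ρ₁⟩` (so `LTF²⟨ρ₁⟩²N = χ` identically), and
`var(S)` the population variance of catalog sizes. The naive branching
ratio averages second-bin over first-bin event counts across *all*
avalanches (zero for duration-1 ones; conditioning on survival into a
second bin overestimates the ratio by ~e^σ/(e^σ−1) at small counts). The
multistep-regression estimator computes lag slopes
`r_k = cov(a_t, a_{t+k})/var(a_t)` for `k = 1..40` and fits `A·m^k` by
nonlinear least squares in linear space; fitting in log space instead
(available via `fit_space="log"`) is biased upward by skewed log-noise at
long lags and fails a 0.9-ground-truth round trip. A noise-floor guard
(`max r_k < 4/√n`) rejects series with no temporal structure.

## Scaling line and position

The cohort line is an OLS fit of τ̃_T on τ̃_S (≥3 subjects). Positions
shift every pair vertically by the line's intercept, project onto the unit
vector along the line, and divide by the cohort maximum — values in [0, 1]
with the maximum exactly 1. Positions are *cohort-relative*: comparing
subjects across cohorts requires jointly normalising them. Subjects whose
fits fail anywhere in the chain are excluded (with logged reasons) before
the line fit.

## Susceptibility sweeps

`kappa_sweep` runs `reps` fresh simulations per grid point and reports the
per-κ mean and SD of χ. The quasicritical peak is broad relative to
run-to-run noise, so besides the raw argmax the package exposes the vertex
of a quadratic fit to χ(κ) (`kappa_star_quadratic`), which is the
recommended peak-location estimate and the one used in the calibration of
the cohort generator.

## Synthetic cohort generator

The generator emulates a resting-state MEG aging cohort structurally, not
biophysically. Study conditions (defaults): 102 channels at 1 kHz, 520 s
per subject, ages uniform on 18–88, gender labels alternating down the
age-sorted roster. Age maps linearly to bias, `B(18) = 0.6` to
`B(88) = 1.8` — the two endpoints are the simulated bias levels that
bracket the aging contrast, and the linear interpolation is a modelling
choice motivated by the monotone steepening of connection-strength
profiles with age; per-subject κ is pinned to the susceptibility peak for
that bias (quasicritical homeostasis), interpolated between peaks located
by cached coarse sweeps at the endpoint biases (internal fixed calibration
seed, so the map is identical for every cohort; `kappa_override` fixes κ
globally instead).

Sensor model: node event trains are thinned to a `detection_prob = 0.05`
random subset (MEG sensors see only a small fraction of neural events —
without thinning, z-scoring buries single events below the 3 SD threshold
and coincidence-merging clips exactly the large avalanches), pooled
round-robin onto channels, convolved with a 3-sample raised-cosine pulse
of amplitude 10, and summed with Gaussian noise of SD 1. What this does
*not* emulate: MEG forward fields, 1/f background spectra, artifacts,
sensor correlations, or any physiological timescale mapping — so passing
cohort tests demonstrates that the *pipeline* recovers the built-in
bias-driven trends through a sensor-like observation chain, not that it
would behave identically on real MEG.

With defaults, the full chain reproduces the expected trend pattern:
position on the line falls with age, susceptibility rises with age, and
position anti-correlates with susceptibility.

## Per-subject analysis chain

z-score per channel (constant channels raise a named error; NaNs are
rejected at load) → events at ±3 SD, one per excursion at its absolute
extremum (earliest sample on ties) → bin width = rounded mean inter-event
interval of the pooled event train (floor 1 sample; overridable) →
avalanche catalog → physical-window exponent fits with
`system_size = n_channels` → activity statistics on the binned raster.
Cohort statistics are Pearson correlations (var(S) on a log₁₀ scale) and a
Welch two-tailed t-test of position by gender label; no multiple-testing
correction is applied.

## Problem sizes used in the shipped checks

Reference-cell ensembles use 6 runs × (5×10⁶ steps or 5×10⁴ avalanches)
in the acceptance script and 4 × (4×10⁶ steps or 5×10⁴ avalanches) in
the test suite; sweep checks use 3 reps × 8×10⁵ steps on 0.01-spaced
grids; branching-process oracles use N = 2048 and 10⁴ seeded avalanches;
cohort-trend checks use ten 40-subject cohorts at 45 s per recording.
These sizes were chosen so the estimator spread (run-to-run SD) is small
against the effects being checked.

## Known limitations

* The duration-exponent estimate is the most window-sensitive quantity;
  single short runs scatter by ±0.1–0.15 and should always be
  ensemble-averaged.
* χ at strong bias is slowly mixing; comparisons across studies must match
  window lengths.
* Positions have no error bars and are cohort-relative by construction.
* The generator's aging model varies only the weight bias `B`; spontaneous
  activity `p_s` is held fixed (an override exists for sensitivity
  studies).
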