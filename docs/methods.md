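# Methods

This note documents the models implemented in `capturestress`, the
parameters that matter, the synthetic-data generator used for validation,
and the numerical and design choices made where the problem left them open.

## Signal model and features

Tri-axial acceleration (g, 1 Hz) is reduced to the vectorial sum
VS = √(x² + y² + z²). VS is preferred over dynamic-body-acceleration
metrics here because a gangion-mounted logger's orientation cannot be
standardised across animals; VS is invariant to axis permutation and sign
flips, which the test suite asserts as a property.

Features are computed on sliding windows of the VS series:

* **amplitude** (g): peak-to-trough range of VS in the window. Range — not
  half-range, not a baseline-removed magnitude — is the definition used
  throughout, because only range makes a 0.05 g threshold meaningful
  against the ~1 g static gravity component. This is stated prominently
  since "amplitude" is otherwise ambiguous.
* **cycle** (s): mean interval between local maxima of the mean-removed VS
  whose prominence exceeds 25% of the window amplitude. Fewer than two
  qualifying peaks yields a no-cycle sentinel mapped to the window length,
  which always compares as "> 5 s" downstream. At 1 Hz, periods below 2 s
  are unresolvable (Nyquist); estimates below 2 s are floored at 2 s and
  flagged.

**Window length.** Default 10 s with 50% overlap. Two constraints pull in
opposite directions: the window must hold at least two peak intervals of a
just-sub-cutoff (≈5 s) cycle, which sets the 10 s floor, while per-second
levels are produced by expanding window labels (later window wins on
overlap), so every second covered by a bout-boundary-spanning window
inherits the more intense level — the expected resting-time erosion per
boundary equals the window length. The 10 s minimum therefore also
minimises the systematic downward bias of the resting proportion
(measured at ≈ −0.007 on synthetic events, versus −0.019 at 30 s).

## Intensity classification

Each individual's windows are clustered separately (k-means, k = 3,
10 restarts, fixed seed), matching the per-individual design of the field
protocol: clustering across individuals would let one animal's extreme
behaviour shift everyone's clusters. Not every animal exhibits all three
levels, so k collapses to the number of distinct feature points when the
event is degenerate, and two clusters may map to the same level.

**Clustering feature.** The default feature is z-scored
log(amplitude + 0.05 g). The log reflects the multiplicative spacing of
the cutoffs (0.05 g, 0.25 g) and prevents the wide high-intensity
amplitude range from absorbing two of the three clusters; the offset —
the smallest decision threshold — compresses sub-threshold variation such
as logger quantization noise in resting bouts, which otherwise splits the
resting windows into "exactly constant" and "one-bin flicker" clusters.
A 2-D alternative, z-scored (amplitude, log cycle), is available
(`cluster_features="amplitude_cycle"`) but is not the default: the
no-cycle sentinel common in resting windows forms an artificial cluster
on the cycle axis and degrades level recovery badly on synthetic events.
Cluster indices are canonicalised by ascending median amplitude, so output
is invariant to k-means' internal label permutation.

**Level assignment.** Cutoffs are applied to each cluster's median
(amplitude, cycle) — cluster-then-assign, avoiding window-level label
chatter; a window-level mode exists behind `level_mode="window"`. The
rules: high if amplitude > 0.25 g and cycle < 5 s; low if amplitude
< 0.05 g; medium otherwise, which includes large-amplitude slow signal
(> 0.25 g with > 5 s cycle). Boundary equality (amplitude exactly 0.05 or
0.25 g, cycle exactly 5 s) is assigned to medium: the strict inequalities
leave boundaries undefined, and medium is the conservative middle.

**Metrics.** p_low/p_med/p_high are labelled-second fractions; p_high is
computed as 1 − p_low − p_med so the budget sums to one exactly in
floating point. Mean fight intensity is ΣVS over the event divided by
capture duration (g·min⁻¹); capture duration comes from the hook timer in
the deployment table, never from trace length, since loggers record before
and after hooking. Optional trim offsets are the user's responsibility —
how trace ends were aligned to hook-timer events is not standardised.

## Blood-panel preparation

Point-of-care analysers measure pH at 37 °C; correction to water
temperature (a proxy for body temperature) is `ph37 + slope · (37 − SST)`
with a literature-supplied slope. The default mode is the identity with a
logged notice: no universal slope is defensible, published
species-independent conversions are external to this package, and current
best practice corrects on the instrument. Hyperkalemia is flagged when
plasma K⁺ strictly exceeds 7.0 mmol l⁻¹; a missing K⁺ yields a missing
flag, never `False`. Panel validation rejects impossible values (negative
concentrations, haematocrit outside [0, 100]) and warns on values outside
configurable plausibility ranges (defaults: observed spans widened by 50%).

## Endpoint models and inference

Each endpoint is fit by OLS on complete cases for that endpoint (so n
varies by response, as in real panels with assay failures) with four
covariates: logit(p_low), capture duration (min), SST (°C), TL (cm),
unstandardised. The proportion enters through the logit,
log(p / (1 − p)) — the log-ratio of resting versus non-resting time, the
natural reference split when only p_low enters the model; an
additive-log-ratio variant log(p_low / p_high) is available. Proportions
at 0 or 1 are clamped to ε = 1/(2·n_seconds) when the event length is
known (1e-6 otherwise).

Intervals come from the standard noninformative-prior posterior simulation
for the normal linear model: draw σ² = (n−k)s²/χ²₍n−k₎, then
β ~ N(β̂, σ²(XᵀX)⁻¹); the 2.5/97.5 empirical percentiles of 1000 draws
form the 95% interval and a term is "significant" when the interval
excludes zero. With a fixed seed the procedure is exactly reproducible.
The tests verify that these intervals converge to classical t intervals
(they are the same distribution in the large-draw limit), control type-I
error at ≈5% on a true-zero coefficient, and cover generating coefficients
at ≈95%. No multiple-testing correction is applied across the eight
endpoints per species — a deliberate match to the analysis this package
operationalises, and a caveat for interpretation.

Rank-deficient designs raise an error naming the collinear terms;
fitting requires at least k + 2 rows for k coefficients.

## Synthetic-data generator

The generator exists so that every downstream stage can be validated
against known truth; its defaults are chosen once, on field realism, and
are the conditions under which the validation suite runs.

**Bout structure.** Per-second levels follow a three-state Markov chain
specified by mean sojourns of 600 s (resting), 300 s (aggravated
swimming) and 120 s (struggling), with jump preferences favouring
adjacent levels; implied stationary occupancy ≈ (0.62, 0.31, 0.07). The
chain is simulated at the embedded-jump level (geometric sojourns plus
jump draws), which is distribution-identical to per-second stepping.
Simulated events average p_low ≈ 0.55 with across-event SD ≈ 0.14,
matching published descriptive statistics for the study species
(p_low ≈ 53% ± 14). Capture durations draw uniformly from the observed
field range, 2.57–264.88 min.

**Front-loaded struggling** (on by default): the high-state weight in the
initial-state and jump draws is multiplied by 1 + 30·exp(−t/300 s).
Captures therefore begin struggle-heavy and relax toward stationarity
within ~10–15 min. This is what produces the negative relationship
between mean fight intensity and capture duration that the validation
suite checks; with the boost off the chain is exactly homogeneous.

**Waveform.** Within a bout, VS = 1 g + A/2 + (A/2)·sin(2πt/T + φ) with
per-bout draws of range A and period T. The oscillation lifts VS above
the static 1 g baseline rather than straddling it: the vector magnitude
of gravity plus dynamic acceleration is rectified, so mean VS rises
during activity — without this, mean fight intensity would be constant
regardless of behaviour. Level defaults: A ~ N(0.01, 0.003) g (low),
N(0.15, 0.03) g (med), N(0.50, 0.07) g (high); T ~ N(8, 2) s (low),
N(3.5, 0.8) s (med), N(3.0, 0.5) s (high). Amplitudes were chosen to
straddle the cutoffs with ≥3-SD separation *in the observed feature
space*: the resting amplitude is set below one quantization step so that
component rounding (which adds up to ~0.04 g of apparent VS range when an
oscillation rides a bin boundary) cannot push resting windows across the
0.05 g cutoff. Period draws are clipped per level — in particular the
high state to [2.5, 4.0] s — because a 4.5–5 s period discretized at 1 Hz
produces peak spacings of exactly 5 samples, which the strict "< 5 s"
rule would read as medium; a simulated struggle must exhibit its defining
signature after sampling. The no-calibration caveat stands: the source
field study reports cutoffs, not per-level amplitude/cycle distributions,
so these defaults are plausible rather than estimated.

**Logger model.** The VS target is projected onto a fixed random unit
orientation per event (hooking orientation is uncontrolled in the field),
each component is quantized to 0.025 g and clipped to ±3 g. Quantized
trace values are exact multiples of the resolution; the reconstructed VS
matches the target to within ~0.02 g.

**Physiology.** Each endpoint is intercept + β·(logit p_low, duration,
SST, TL) + Gaussian noise. Species presets calibrate target means and
total SDs to published descriptive tables for nurse and Caribbean reef
sharks; slopes for the relationships reported as significant in the field
(nurse: pH ↑ with logit p_low and duration, glucose and K⁺ ↑ with SST,
K⁺ ↓ with TL; reef: lactate ↑ and Cl⁻ ↓ with duration) are set to the
midpoints of the published interval estimates, other slopes to zero, and
residual SDs back-solved so total endpoint SDs approximate the tables.
Intercepts are derived from the target mean at the generator's covariate
means. Concentrations are truncated at zero (negligible mass at the
defaults); with residual SD 0 an endpoint equals its linear predictor
exactly, which the tests assert.

**Seeding.** A single master seed feeds a `SeedSequence`; children 0…n−1
drive the per-event traces, child n the covariate draws, child n+1 the
blood panels. Identical config and seed reproduce studies byte-for-byte.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: no hydrodynamic or biomechanical realism (pure
sinusoids, not swimming kinematics); no logger drop-outs, time gaps or
hook-timer failure; no gear-check disturbance every 30 min; no
species-level behavioural differences in the bout model; physiology is
linear-Gaussian with exactly the modelled covariates, so model
misspecification is untested by construction. Recovery rates measured on
synthetic events (≈98% per-second label accuracy, |p̂_low − p_low| well
under 0.05) are upper bounds on field performance.

## Numerical details

* Windows are half-open [start, end); the final window is anchored at the
  trace end so every sample is labelled; a trace shorter than one window
  becomes a single full-trace window with a warning.
* Identical feature points collapse k; a single distinct point skips
  k-means entirely.
* Empirical percentiles (linear interpolation) are used for interval
  bounds; fewer than 100 draws triggers a warning.
* Readers clip out-of-range samples to ±3 g and count them in a logged
  warning; non-monotone timestamps are an error naming the first
  offending row; missing blood cells stay missing end-to-end.
* Validation sizes were chosen to keep the full suite and the acceptance
  script each under a minute on one CPU: 40 events for label recovery,
  500 replicates for coverage and type-I error, 200 studies of 35 sharks
  for the qualitative-sign checks, 2000 rows / 20000 draws for the
  t-interval comparison.

## Known limitations

* The cutoffs are taken as given; the package does not re-derive them
  from data, and the cluster-median rule inherits their sharpness —
  clusters sitting on a boundary flip level with small perturbations.
* Per-second labels near bout boundaries inherit the more intense level
  of any window spanning the boundary; the resting proportion carries a
  small negative bias (≈ −0.01 at defaults) as a result.
* 1 Hz sampling cannot resolve cycles below 2 s, and periods near an
  integer multiple of the sampling interval alias; cycle estimates are
  coarse by construction.
* Complete-case fitting assumes panel missingness is unrelated to the
  endpoints (assay failure, not biology).
* The posterior-simulation intervals are exact only under the normal
  linear model; no robustness to heteroscedasticity or outliers is
  claimed, and no multiple-testing correction is applied.
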