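# Methods

This note documents the models and procedures `cardioday` implements,
the synthetic-data generator that drives its tests, and the numerical
and design choices made where more than one defensible option existed.

## Signal quality

Beat detection is a Pan–Tompkins-style chain: 2nd-order Butterworth
band-pass 5–18 Hz (zero-phase), squared derivative, 150-ms moving
integration, peak picking above an adaptive threshold (30 % of the
2.5-s local envelope, floored at 8× the global median of the integrated
signal so noise-only stretches produce no beats), refinement to the
sharpest deflection of the band-passed signal within ±80 ms, and a
250-ms refractory period. The threshold is proportional to signal
level, so detection is invariant to overall gain; this is verified by a
generator/detector round-trip test (beat times recovered within
±20 ms).

Each 10-s segment is labelled by a two-step quality indicator. Step 1
applies three RR-interval rules: segment mean HR within 40–180 bpm, no
RR interval above 3 s, and max(RR)/min(RR) ≤ 2.2. The HR rule is
operationalised on the segment *mean* HR (60000/mean RR) rather than
instantaneous rates, for robustness; the ratio rule is implemented as
max/min > 2.2 ⇒ fail, the only coherent reading since a min/max ratio
cannot exceed 1. A segment with fewer than two detected beats fails all
rules. Step 2 — run only when step 1 passes, so artifacts never
contaminate the template — correlates each beat (window ±0.35× the
segment median RR) with an adaptive template updated by exponential
averaging (rate 0.1) on passing segments; the segment passes at mean
Pearson correlation ≥ 0.66. The threshold and window follow the
template-matching quality-assessment literature for ambulatory ECG and
are exposed in `TemplateMatcher`. An uninitialised template is seeded
from the current segment's mean beat, which then must be self-similar
to pass; after 5 consecutive failures the template resets.

## Features and filtering

Mean HR is defined as 60000/mean(RR in ms) — one convention used
everywhere, including the QI range rule. RMSSD is √mean(ΔRR²). Both
are computed in 5-min windows stepping by 1 min; a window's RR set
contains every interval whose defining beat pair lies fully inside the
window, avoiding edge double-counting. Activity is the SD of the
3-axis acceleration magnitude per window. Retention is strict on both
printed inequalities: windows are dropped when mean QI < 0.8 or std
ACC > 0.04 g, so a window at exactly 0.8/0.04 is retained. Retained
windows are averaged per subject × clock hour (or 6-h block, or a named
period: day 12:00–18:00, night 00:00–06:00, hour 2–3) across all
recording days, then log-transformed (natural log). Averaging before
the log is the default because the analysis dataset is filtered first
and logged once; the opposite order is available by logging window
features upstream. Clock hours derive from the recording's start time
by the window's start; no DST adjustment is applied within a recording.
The general activity index is the magnitude SD over the *entire*
recording with no filtering.

## Circadian mixed model

The modelling unit is the subject × clock-hour aggregate on the log
scale. The full fixed-effect design is: group (control = 0,
patient = 1), standardised age, sex (female = 0), standardised BMI,
standardised overall activity index, sin/cos of the 24-h and 12-h
harmonics of clock hour, and the four group × harmonic products; the
random effect is a subject intercept. t is the integer clock hour,
matching the hourly aggregation.

Fitting uses `statsmodels` MixedLM (BFGS, with a Powell retry at
degenerate variance optima). ML is used during stepwise comparisons and
REML for final fits. p-values are Wald t statistics referred to a t
distribution with residual degrees of freedom (n_obs − n_fixed);
Satterthwaite degrees of freedom are not available in the backend, and
with thousands of records the difference is negligible. Conditional R²
follows Nakagawa: (var(Xβ) + σ²_u) / (var(Xβ) + σ²_u + σ²_e).

Backwards stepwise removes, at each round, the least significant
removable term with p > 0.05. Group is never removed; a harmonic main
effect is removable only once no retained interaction contains it
(marginality); covariates leave freely. The selected model is refitted
by REML. Amplitudes are amp24 = √(β_s24² + β_c24²) (ditto 12 h), with
interaction coefficients added for the patient curve; peak-to-trough is
evaluated on a 1-min grid. The optional sleep-quality check adds a
binary covariate to the retained model restricted to day or night
records and reports its estimate/t/p.

## Classification

Each subject contributes one row of period means (log HR, log RMSSD, or
both). For each leave-one-out fold a logistic regression is fitted on
the n−1 training subjects, with features standardised by the training
fold's own mean/SD so the held-out subject never influences scaling.
The held-out probability is thresholded at 0.5; an exact tie predicts
the patient class. On perfect separation or non-convergence the fold
falls back to a weakly ridge-penalised fit (C = 10⁴) rather than
failing. Accuracy and Cohen's κ = (p_o − p_e)/(1 − p_e) are computed
from the held-out confusion table only. With balanced classes p_e is
exactly 0.5, so κ = 2·accuracy − 1.

A caveat documented here because the tests rely on it: LOOCV accuracy
under label permutation is *below* 0.5 in expectation for small n (the
training majority systematically opposes the held-out label); at
n = 32 the permutation-null mean is ≈ 0.35. The null check therefore
uses the band 0.5 ± 3·√(0.25/32), the sampling SE of a single
32-subject accuracy, not the SE of the permutation mean.

## Clinical statistics

Two-sample t tests from printed summaries use the pooled-variance
formula (identical to Welch at equal n). The 2×2 chi-square is Pearson
without continuity correction; printed percentages are converted to
counts by rounding pct × n. Responders are patients with ≥ 30 % HRSD
reduction at 24 h (inclusive at exactly 30 %). The baseline-HR outlier
rule excludes values strictly above mean + 2 SD of the analysis set.
Spearman correlations report a 95 % CI via the Fisher transform with
the 1.06/(n−3) variance inflation (bootstrap optional); the
responder/non-responder baseline difference uses a percentile
bootstrap. The treatment-phase model adds a pre/post fixed effect
(optionally phase × ketamine) to the retained circadian terms, fitted
on patients with both phases.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not ECG physiology. Instantaneous HR follows
mesor + amp24·cos(2π(t−acro24)/24) + amp12·cos(2π(t−acro12)/12); RR
intervals are 60000/HR(t) plus i.i.d. Gaussian noise with
SD = rmssd(t)/√2, so the expected windowed RMSSD equals the profile's
target (for i.i.d. noise E[RMSSD] = √2·SD — the closed-form oracle the
calibration tests use). `noise_sd` adds a slow Ornstein–Uhlenbeck RR
wander (τ = 5 min, updated per 60-s chunk) that perturbs HR level
without touching successive differences. Day-to-day within-subject
variance is 0 by default and is not currently parameterised beyond the
wander. Generation is chunked per minute with HR frozen within a
chunk; RR is clipped to [300, 3000] ms so beat times stay strictly
increasing. Profiles whose deterministic curve leaves 40–180 bpm are
rejected.

Group defaults are calibrated to the target cohort: control mesor
62.44 bpm (between-subject SD 5.33), RMSSD 69.64 ms (SD 20.5); patient
77.79 bpm (SD 9.53), 38.88 ms (SD 14.34). Circadian amplitudes and
acrophases derive from the published log-scale harmonic coefficients
mapped to natural units (amp_bpm ≈ mesor × log-amplitude): control
amp24 8.7 bpm peaking at 15.4 h, patient 6.1 bpm — the patients'
flatter rhythm — with 12-h amplitudes 2.3/1.4 bpm and RMSSD 24-h
modulation 1.0/4.3 ms. Per-subject profiles are drawn from the group
Normals (mesor clipped so the curve respects the 40–180 bpm bound).
One master seed spawns independent per-subject substreams, so cohorts
are reproducible and subjects independent.

Rendered ECG places a Ricker-wavelet QRS surrogate (width 22 ms, peak
1 mV) at each beat over 0.25-Hz baseline wander (0.05 mV) and white
noise (0.02 mV). There are no P/T waves or respiratory modulation —
the rendering exists to exercise detection and template matching, and
passing tests show the pipeline handles signals of this structure, not
arbitrary clinical ECG morphology. Artifact injection corrupts a
target fraction of the signal in ~10-s events — dropout (flat zero),
spike trains (~0.4-s impulse spacing, producing implausible RR
structure), or morphology corruption (band-limited noise at matched
power) — and returns the ground-truth mask used to score QI sensitivity
and specificity.

Acceleration is 1 g of gravity plus white noise scaled by a diurnal
level: day (08:00–22:00) levels drawn per 5-min epoch from a gamma
distribution (shape 2) so that a realistic fraction of day windows
passes the 0.04 g filter, constant night level 0.01 g. Day means
(0.053/0.031 g for controls/patients) were chosen so the overall
unfiltered activity index lands near the cohort's printed 0.05/0.03 g.

For model-level studies, `simulate_hourly_cohort` generates subject ×
hour records directly from the mixed model (the estimand is then the
generating coefficient vector itself), and `simulate_period_features`
draws per-subject period means from the group moments shifted by the
group profile curve averaged over the period — at night both groups
drop, controls further than patients, which is what makes night the
best classification window.

## Problem sizes

Parameter recovery runs 100 replicates of 16 + 16 subjects × 4 days at
the hourly level; classification power uses 50 cohort draws and a
200-permutation null; QI validation uses a 10-min rendered recording
per artifact class at 25 % corruption; the beat-level end-to-end run
uses 16 + 16 subjects × 2 days with 8-Hz acceleration. These sizes give
Monte-Carlo error comfortably below the tolerances tested while keeping
the default suite fast.

## Known limitations

- The QRS detector and template matcher are validated against the
  package's own renderer, not against clinical recordings or annotated
  databases.
- The hourly-record residual in beat-level simulations is smaller than
  in real data (no unmodelled hour-scale physiology), so conditional R²
  on synthetic cohorts runs near 1 rather than the 0.5–0.8 typical of
  field data.
- MixedLM provides no Satterthwaite/Kenward-Roger corrections; with few
  subjects and many records the Wald-t p-values are mildly liberal for
  between-subject effects.
- The EDF reader handles single-rate multi-channel files via MNE;
  vendor-specific binary exports are out of scope.
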