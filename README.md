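# cardioday

24-hour wearable-ECG analysis of circadian heart-rate dynamics in
depression: signal-quality indication, windowed HR/RMSSD feature
extraction with activity filtering, harmonic (cosinor) mixed-effects
modelling, day/night classification, and treatment-response statistics —
plus a synthetic cohort generator so the entire pipeline is testable
without any recordings on disk.

## The problem

Patients with major depressive disorder show higher heart rate (HR) and
lower heart-rate variability (HRV) than healthy controls, and their
circadian HR rhythm is flattened. Ambulatory chest-patch ECG (2-lead,
256 Hz, with 32-Hz 3-axis acceleration) makes it possible to measure
this over several days of ordinary life — if motion artifacts are
removed and activity is controlled for. `cardioday` implements that
analysis end to end, for researchers working with long-term wearable
ECG in psychiatry or chronobiology.

## The model

Beats are detected with a Pan–Tompkins-style QRS detector. Every 10-s
segment receives a binary quality indicator (QI): it must pass three RR
plausibility rules — mean HR in [40, 180] bpm, no RR gap > 3 s, max/min
RR ratio ≤ 2.2 — and then adaptive QRS template matching (mean beat
correlation ≥ 0.66). Mean HR (60000/mean RR, bpm) and RMSSD
(√mean(ΔRR²), ms) are computed in 5-min windows sliding by 1 min;
windows with mean QI < 0.8 or acceleration-magnitude SD > 0.04 g are
excluded, and retained windows are averaged per subject × clock hour and
log-transformed.

Hourly log HR (or log RMSSD) is then modelled with a random-intercept
linear mixed model with dual-harmonic circadian terms,

y_ih = β₀ + β_g·group + covariates
  + β₁ sin(2πh/24) + β₂ cos(2πh/24) + β₃ sin(2πh/12) + β₄ cos(2πh/12)
  + group × harmonics + u_i + ε_ih,

selected by backwards stepwise elimination on p-values (marginality
enforced). The 24-h amplitude is √(β₁² + β₂²), with the group
interactions added for the patient curve. Group membership is
classified from day (12:00–18:00), night (00:00–06:00) and hour 2–3
aggregates by leave-one-out cross-validated logistic regression,
summarised as accuracy and Cohen's κ. The clinical module covers
responder labelling (≥ 30 % HRSD reduction at 24 h), the baseline-HR
outlier rule (> mean + 2 SD), Spearman response correlations, and the
pre/post treatment-phase mixed model.

## Worked example

```python
import numpy as np
from cardioday.synthetic_data import CohortSpec, simulate_cohort
from cardioday.pipeline import cohort_hourly, cohort_period_features, meta_frame
from cardioday.circadian_model import build_design, backward_stepwise, amplitude_summary
from cardioday.classification import loocv_logistic

spec = CohortSpec(n_controls=8, n_patients=8, days=2, seed=1, acc_fs=8.0)
recordings, metas = simulate_cohort(spec)
hourly, coverage = cohort_hourly(recordings)
fit = backward_stepwise(build_design(hourly, meta_frame(metas, recordings)), "log_hr")
print("group effect (log HR):", round(fit.term("group")[0], 3))
print("control amp24:", round(amplitude_summary(fit, "control")["amp24"], 3))
print("patient amp24:", round(amplitude_summary(fit, "patient")["amp24"], 3))

night = cohort_period_features(recordings)["night"]
print("night LOOCV accuracy:", loocv_logistic(night, ["log_hr"]).accuracy)
```

Output:

```
group effect (log HR): 0.194
control amp24: 0.148
patient amp24: 0.085
night LOOCV accuracy: 0.75
```

The group effect says patients run ~19 % higher HR than controls on the
log scale in this draw (the generator's target is 0.221, i.e. the
77.79 vs 62.44 bpm group means); the patient 24-h amplitude is roughly
half the control amplitude; and night HR classifies 12 of the 16
subjects correctly under leave-one-out cross-validation — a small-cohort
draw; at the full 16 + 16 size the median night accuracy is 90.6 %.

A command-line interface mirrors the library
(`cardioday simulate|qc|features|model|classify|respond`).

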