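"""Synthetic cohorts of 24-h ECG/ACC recordings with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: per-subject instantaneous heart rate follows a dual-harmonic
circadian curve

    HR(t) = mesor + amp24*cos(2*pi*(t - acro24)/24)
                  + amp12*cos(2*pi*(t - acro12)/12)    [t in clock hours]

and RR intervals are drawn as RR(t) = 60000/HR(t) plus i.i.d. Gaussian
beat-to-beat noise with SD = rmssd(t)/sqrt(2), so that the expected
windowed RMSSD equals the profile's rmssd target (for i.i.d. noise,
E[RMSSD] = sqrt(2)*SD — the closed-form oracle used by the tests).
``noise_sd`` adds a slow Ornstein–Uhlenbeck RR wander (minutes-scale)
that perturbs HR without touching successive differences, mimicking
low-frequency HR variability.

Default group profiles are calibrated to the trial cohort this pipeline
targets: controls with 24-h mean HR 62.44 bpm (SD 5.33) and RMSSD
69.64 ms (SD 20.5); patients 77.79 bpm (SD 9.53) and 38.88 ms
(SD 14.34); circadian amplitudes derived from the published log-scale
harmonic coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import SubjectMeta
from .signal_quality import BeatSeries

__all__ = [
    "CircadianProfile",
    "CohortSpec",
    "SubjectRecording",
    "CONTROL_PROFILE",
    "PATIENT_PROFILE",
    "DEFAULT_LOGHR_COEFS",
    "simulate_beat_series",
    "render_ecg",
    "inject_artifacts",
    "simulate_activity",
    "simulate_cohort",
    "simulate_hourly_cohort",
    "simulate_period_features",
]


@dataclass(frozen=True)
class CircadianProfile:
    """Generative circadian parameters for one group (or one subject).

    Units: bpm for HR quantities, ms for RMSSD quantities, clock hours
    for acrophases.  `mesor_sd_hr` and `rmssd_sd` are between-subject
    SDs used when drawing individual subjects from a group profile.
    """

    mesor_hr: float
    amp24_hr: float = 0.0
    amp12_hr: float = 0.0
    acrophase24: float = 0.0
    acrophase12: float = 0.0
    rmssd_level: float = 40.0
    rmssd_amp24: float = 0.0
    noise_sd: float = 0.0
    mesor_sd_hr: float = 0.0
    rmssd_sd: float = 0.0

    def __post_init__(self) -> None:
        if not 40 <= self.mesor_hr <= 180:
            raise ValueError("mesor_hr outside [40, 180] bpm")
        for name in ("amp24_hr", "amp12_hr", "rmssd_level", "rmssd_amp24", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("acrophase24", "acrophase12"):
            if not 0 <= getattr(self, name) < 24:
                raise ValueError(f"{name} must lie in [0, 24)")

    def hr_at(self, t_hours):
        """Instantaneous HR (bpm) at clock time `t_hours`."""
        t = np.asarray(t_hours, dtype=float)
        return (
            self.mesor_hr
            + self.amp24_hr * np.cos(2 * np.pi * (t - self.acrophase24) / 24)
            + self.amp12_hr * np.cos(2 * np.pi * (t - self.acrophase12) / 12)
        )

    def rmssd_at(self, t_hours):
        """Target windowed RMSSD (ms) at clock time `t_hours`."""
        t = np.asarray(t_hours, dtype=float)
        level = self.rmssd_level + self.rmssd_amp24 * np.cos(
            2 * np.pi * (t - self.acrophase24) / 24
        )
        return np.maximum(level, 0.0)


# group profiles calibrated to the target cohort's printed moments and the
# log-scale harmonic fit (amplitudes mapped to bpm/ms via amp ~ mesor * log-amp)
CONTROL_PROFILE = CircadianProfile(
    mesor_hr=62.44,
    amp24_hr=8.7,
    amp12_hr=2.3,
    acrophase24=15.4,
    acrophase12=9.9,
    rmssd_level=69.64,
    rmssd_amp24=1.0,
    noise_sd=15.0,
    mesor_sd_hr=5.33,
    rmssd_sd=20.5,
)
PATIENT_PROFILE = CircadianProfile(
    mesor_hr=77.79,
    amp24_hr=6.1,
    amp12_hr=1.4,
    acrophase24=16.4,
    acrophase12=11.3,
    rmssd_level=38.88,
    rmssd_amp24=4.3,
    noise_sd=15.0,
    mesor_sd_hr=9.53,
    rmssd_sd=14.34,
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated two-group cohort."""

    n_controls: int = 16
    n_patients: int = 16
    control_profile: CircadianProfile = CONTROL_PROFILE
    patient_profile: CircadianProfile = PATIENT_PROFILE
    days: int = 4
    artifact_rate: float = 0.0  # corrupted fraction of each hour
    seed: int = 0
    start_hour: float = 0.0
    acc_fs: float = 32.0
    # day levels chosen so the overall unfiltered activity index lands near
    # 0.05 (controls) and 0.03 (patients) with epoch-varying day activity
    day_activity: tuple[float, float] = (0.053, 0.031)  # control, patient
    night_activity: float = 0.01
    activity_epoch_shape: float = 2.0
    post_phase: bool = False
    post_loghr_drop: float = 0.03  # log-scale HR reduction in the post phase

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_patients < 1 or self.days < 1:
            raise ValueError("counts and days must be >= 1")
        if not 0 <= self.artifact_rate <= 1:
            raise ValueError("artifact_rate must lie in [0, 1]")


@dataclass
class SubjectRecording:
    """In-memory recording of one subject in one phase."""

    meta: SubjectMeta
    beats: BeatSeries
    acc: np.ndarray | None = None
    acc_fs: float | None = None
    start_hour: float = 0.0
    profile: CircadianProfile | None = None
    phase: str = "pre"


def simulate_beat_series(
    profile: CircadianProfile,
    days: int,
    seed: int | np.random.Generator = 0,
    start_hour: float = 0.0,
) -> BeatSeries:
    """Draw a beat-time series from a circadian profile.

    RR intervals follow RR(t) = 60000/HR(t) + slow OU wander +
    N(0, rmssd(t)^2/2) white noise, clipped to [300, 3000] ms so beat
    times stay strictly increasing.  Raises if the deterministic HR
    curve leaves [40, 180] bpm anywhere.
    """
    grid = np.linspace(0, 24, 24 * 60, endpoint=False)
    hr_grid = profile.hr_at(grid)
    if hr_grid.min() < 40 or hr_grid.max() > 180:
        raise ValueError(
            f"profile HR range [{hr_grid.min():.1f}, {hr_grid.max():.1f}] leaves [40, 180] bpm"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    total_s = days * 86400.0
    chunk = 60.0
    tau = 300.0  # OU time constant, s
    rho = np.exp(-chunk / tau)
    wander = 0.0
    t = 0.0
    times: list[np.ndarray] = []
    while t < total_s:
        clock = (start_hour + t / 3600.0) % 24
        rr_mean = 60000.0 / float(profile.hr_at(clock))
        sigma = float(profile.rmssd_at(clock)) / np.sqrt(2.0)
        n = int(np.ceil(chunk * 1000.0 / rr_mean)) + 8
        rr = rr_mean + wander + sigma * rng.standard_normal(n)
        rr = np.clip(rr, 300.0, 3000.0)
        tt = t + np.cumsum(rr) / 1000.0
        stop = min(t + chunk, total_s)
        cut = int(np.searchsorted(tt, stop, side="left"))
        if cut == 0:
            cut = 1
        times.append(tt[:cut])
        t = float(tt[cut - 1]) if cut <= tt.size else float(tt[-1])
        if t >= total_s:
            break
        wander = rho * wander + np.sqrt(1 - rho**2) * profile.noise_sd * rng.standard_normal()
    beat_times = np.concatenate(times) if times else np.empty(0)
    return BeatSeries(beat_times[beat_times < total_s])


def _qrs_template(fs: float, width_s: float = 0.022) -> np.ndarray:
    """Ricker-wavelet QRS surrogate: sharp positive peak, small side lobes."""
    half = int(round(4 * width_s * fs))
    x = np.arange(-half, half + 1) / fs
    a = width_s
    return (1 - (x / a) ** 2) * np.exp(-(x**2) / (2 * a**2))


def render_ecg(
    beats: BeatSeries,
    fs: float = 256.0,
    seed: int | np.random.Generator = 0,
    duration: float | None = None,
    amplitude_mv: float = 1.0,
    noise_sd_mv: float = 0.02,
    wander_mv: float = 0.05,
) -> np.ndarray:
    """Render an ECG trace by placing a QRS-like template at each beat.

    Adds 0.25-Hz baseline wander and white noise; template peak
    amplitude is far above the noise SD so the detector round-trip is
    well-posed.  With zero beats the output is a pure noise trace.
    """
    if fs < 128:
        raise ValueError("fs must be >= 128 Hz")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if duration is None:
        duration = (float(beats.beat_times[-1]) + 1.0) if len(beats) else 10.0
    n = int(round(duration * fs))
    tmpl = amplitude_mv * _qrs_template(fs)
    half = tmpl.size // 2
    ecg = np.zeros(n)
    for bt in beats.beat_times:
        c = int(round(bt * fs))
        lo, hi = c - half, c + half + 1
        s0, s1 = max(lo, 0), min(hi, n)
        if s1 <= s0:
            continue
        ecg[s0:s1] += tmpl[s0 - lo : tmpl.size - (hi - s1)]
    tt = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    ecg += wander_mv * np.sin(2 * np.pi * 0.25 * tt + phase)
    ecg += noise_sd_mv * rng.standard_normal(n)
    return ecg


def inject_artifacts(
    ecg: np.ndarray,
    fs: float,
    kind: str = "dropout",
    rate: float = 0.1,
    seed: int | np.random.Generator = 0,
    event_s: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a fraction `rate` of the signal; return (ecg, truth mask).

    Kinds: ``dropout`` (flat zero), ``spike`` (large impulses every
    ~0.4 s that masquerade as beats with implausible RR structure),
    ``morphology`` (QRS shapes replaced by band-limited noise of
    similar power).  The boolean mask marks corrupted samples.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    ecg = np.asarray(ecg, dtype=float).copy()
    mask = np.zeros(ecg.size, dtype=bool)
    if rate == 0 or ecg.size == 0:
        return ecg, mask
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ev = int(round(event_s * fs))
    n_events = max(int(round(rate * ecg.size / ev)), 1)
    starts = rng.choice(max(ecg.size - ev, 1), size=n_events, replace=False) if ecg.size > ev else [0]
    amp = float(np.percentile(np.abs(ecg), 99.5)) or 1.0
    for s in np.sort(starts):
        e = min(s + ev, ecg.size)
        if kind == "dropout":
            ecg[s:e] = 0.0
        elif kind == "spike":
            seg = rng.normal(0, 0.05 * amp, e - s)
            step = int(round(0.4 * fs))
            jitter = rng.integers(-step // 3, step // 3 + 1, size=max((e - s) // step, 1))
            for i, pos in enumerate(range(0, e - s - 1, step)):
                p = int(np.clip(pos + jitter[min(i, jitter.size - 1)], 0, e - s - 1))
                seg[p] = 3.0 * amp * (1 if rng.random() < 0.5 else -1)
            ecg[s:e] = seg
        elif kind == "morphology":
            power = float(np.std(ecg[s:e])) or amp / 3
            noise = rng.standard_normal(e - s)
            k = max(int(0.05 * fs), 1)
            smooth = np.convolve(noise, np.ones(k) / k, mode="same")
            ecg[s:e] = power * smooth / (np.std(smooth) or 1.0)
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
        mask[s:e] = True
    return ecg, mask


def simulate_activity(
    days: int,
    day_level: float = 0.053,
    night_level: float = 0.01,
    fs: float = 32.0,
    start_hour: float = 0.0,
    seed: int | np.random.Generator = 0,
    epoch_s: float = 300.0,
    epoch_shape: float = 0.0,
) -> np.ndarray:
    """Simulate 3-axis acceleration (g) with a diurnal activity profile.

    The 5-min magnitude SD averages `day_level` between 08:00 and 22:00
    and `night_level` otherwise.  With ``epoch_shape > 0`` the day-time
    level varies between 5-min epochs (gamma with that shape and mean
    `day_level`), so that a realistic fraction of day windows falls
    under the high-activity exclusion threshold while others exceed it;
    with ``epoch_shape = 0`` the level is constant within day/night.
    The magnitude is 1 g (gravity) plus white noise scaled by the
    current level; all dynamic variation is placed on the z axis.
    """
    if day_level < 0 or night_level < 0:
        raise ValueError("activity levels must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(days * 86400 * fs))
    idx = np.arange(n)
    clock = (start_hour + idx / fs / 3600.0) % 24
    is_day = (clock >= 8) & (clock < 22)
    if epoch_shape > 0 and day_level > 0:
        epoch = (idx // int(round(epoch_s * fs))).astype(np.int64)
        n_epochs = int(epoch[-1]) + 1
        day_draws = rng.gamma(epoch_shape, day_level / epoch_shape, n_epochs)
        level = np.where(is_day, day_draws[epoch], night_level)
    else:
        level = np.where(is_day, day_level, night_level)
    mag = 1.0 + level * rng.standard_normal(n)
    acc = np.zeros((n, 3), dtype=np.float32)
    acc[:, 2] = mag
    return acc


def _draw_subject_profile(group_profile: CircadianProfile, rng: np.random.Generator) -> CircadianProfile:
    margin = group_profile.amp24_hr + group_profile.amp12_hr + 1.0
    mesor = float(
        np.clip(rng.normal(group_profile.mesor_hr, group_profile.mesor_sd_hr), 40 + margin, 180 - margin)
    )
    rms = float(np.clip(rng.normal(group_profile.rmssd_level, group_profile.rmssd_sd), 8, 200))
    return replace(group_profile, mesor_hr=mesor, rmssd_level=rms, mesor_sd_hr=0.0, rmssd_sd=0.0)


def simulate_cohort(spec: CohortSpec) -> tuple[list[SubjectRecording], list[SubjectMeta]]:
    """Simulate a full two-group cohort at the beat level.

    Each subject gets an individual circadian profile drawn from the
    group profile, a beat series over `spec.days` days, a 3-axis ACC
    trace, and group-consistent clinical metadata (controls near
    HRSD 2; patients >= 17, with 24-h-post scores and a 2:1
    ketamine/placebo arm assignment).  Deterministic given `spec.seed`;
    per-subject substreams keep subjects independent.

    When ``spec.post_phase`` is set, each patient additionally gets a
    post-treatment recording with mesor lowered by
    ``post_loghr_drop`` on the log scale.
    """
    ss = np.random.SeedSequence(spec.seed)
    recordings: list[SubjectRecording] = []
    metas: list[SubjectMeta] = []
    groups = ["control"] * spec.n_controls + ["patient"] * spec.n_patients
    children = ss.spawn(len(groups))
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        sid = f"{'C' if group == 'control' else 'P'}{i:03d}"
        gp = spec.control_profile if group == "control" else spec.patient_profile
        prof = _draw_subject_profile(gp, rng)
        beats = simulate_beat_series(prof, spec.days, rng, spec.start_hour)
        day_level = spec.day_activity[0] if group == "control" else spec.day_activity[1]
        acc = simulate_activity(
            spec.days, day_level, spec.night_activity, spec.acc_fs, spec.start_hour, rng,
            epoch_shape=spec.activity_epoch_shape,
        )
        if group == "control":
            hrsd = int(np.clip(np.round(rng.normal(2.12, 2.0)), 0, 10))
            meta = SubjectMeta(
                subject_id=sid, group=group, age=float(np.clip(rng.normal(43.62, 12.57), 18, 75)),
                sex="female" if rng.random() < 0.69 else "male",
                bmi=float(np.clip(rng.normal(24.61, 4.24), 16, 45)),
                hrsd_baseline=hrsd, arm="none", smoker=bool(rng.random() < 0.12),
                sleep_quality=bool(rng.random() < 0.8),
            )
        else:
            hrsd = int(np.clip(np.round(rng.normal(21.88, 4.26)), 17, 40))
            reduction = float(np.clip(rng.normal(0.30, 0.25), -0.2, 0.9))
            meta = SubjectMeta(
                subject_id=sid, group=group, age=float(np.clip(rng.normal(46.0, 12.29), 18, 75)),
                sex="female" if rng.random() < 0.69 else "male",
                bmi=float(np.clip(rng.normal(30.48, 5.24), 16, 50)),
                hrsd_baseline=hrsd,
                hrsd_24h_post=int(np.clip(np.round(hrsd * (1 - reduction)), 0, 40)),
                arm="ketamine" if rng.random() < 2 / 3 else "placebo",
                smoker=bool(rng.random() < 0.19),
                sleep_quality=bool(rng.random() < 0.6),
            )
        metas.append(meta)
        recordings.append(
            SubjectRecording(meta=meta, beats=beats, acc=acc, acc_fs=spec.acc_fs,
                             start_hour=spec.start_hour, profile=prof, phase="pre")
        )
        if spec.post_phase and group == "patient":
            post_prof = replace(prof, mesor_hr=prof.mesor_hr * float(np.exp(-spec.post_loghr_drop)))
            post_beats = simulate_beat_series(post_prof, spec.days, rng, spec.start_hour)
            recordings.append(
                SubjectRecording(meta=meta, beats=post_beats, acc=None, acc_fs=None,
                                 start_hour=spec.start_hour, profile=post_prof, phase="post")
            )
    return recordings, metas


# log-HR fixed effects of the reference harmonic mixed model (patient-coded
# group, standardised age, dual harmonics with group interactions)
DEFAULT_LOGHR_COEFS: dict[str, float] = {
    "const": float(np.log(62.44)),
    "group": 0.221,
    "age_z": -0.176,
    "sex": 0.0,
    "bmi_z": 0.0,
    "activity_z": 0.0,
    "s24": -0.108,
    "c24": -0.087,
    "s12": -0.033,
    "c12": 0.017,
    "group:s24": 0.037,
    "group:c24": 0.055,
    "group:s12": 0.026,
    "group:c12": 0.0,
}


def simulate_hourly_cohort(
    n_controls: int = 16,
    n_patients: int = 16,
    days: int = 4,
    coefs: dict[str, float] | None = None,
    intercept_sd: float = 0.08,
    resid_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate subject x clock-hour log-HR records directly from the
    harmonic mixed model (random intercept per subject).

    This is the cheap generative counterpart of the full beat-level
    pipeline, used for parameter-recovery studies: the returned frame
    has exactly the design columns the model fits, so the generating
    coefficient vector is the estimand.
    """
    coefs = dict(DEFAULT_LOGHR_COEFS if coefs is None else coefs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    n = n_controls + n_patients
    for i in range(n):
        group = 0 if i < n_controls else 1
        u = rng.normal(0, intercept_sd)
        age_z = rng.standard_normal()
        sex = int(rng.random() < 0.31)
        bmi_z = rng.standard_normal()
        act_z = rng.standard_normal()
        for d in range(days):
            for h in range(24):
                t = float(h)
                s24, c24 = np.sin(2 * np.pi * t / 24), np.cos(2 * np.pi * t / 24)
                s12, c12 = np.sin(2 * np.pi * t / 12), np.cos(2 * np.pi * t / 12)
                x = {
                    "const": 1.0, "group": group, "age_z": age_z, "sex": sex,
                    "bmi_z": bmi_z, "activity_z": act_z, "s24": s24, "c24": c24,
                    "s12": s12, "c12": c12, "group:s24": group * s24,
                    "group:c24": group * c24, "group:s12": group * s12,
                    "group:c12": group * c12,
                }
                y = sum(coefs.get(k, 0.0) * v for k, v in x.items())
                y += u + rng.normal(0, resid_sd)
                rows.append({"subject_id": f"S{i:03d}", "clock_hour": h, "day": d,
                             "log_hr": y, **{k: v for k, v in x.items() if k != "const"}})
    df = pd.DataFrame(rows)
    # average the day replicates into one record per subject x clock hour,
    # mirroring the hourly aggregation of the measured pipeline
    keys = ["subject_id", "clock_hour", "group", "age_z", "sex", "bmi_z", "activity_z",
            "s24", "c24", "s12", "c12", "group:s24", "group:c24", "group:s12", "group:c12"]
    return df.groupby(keys, as_index=False)["log_hr"].mean()


def simulate_period_features(
    n_controls: int = 16,
    n_patients: int = 16,
    hr_control: tuple[float, float] = (62.44, 5.33),
    hr_patient: tuple[float, float] = (77.79, 9.53),
    rmssd_control: tuple[float, float] = (69.64, 20.5),
    rmssd_patient: tuple[float, float] = (38.88, 14.34),
    within_sd_frac: float = 0.0,
    period: str | None = "night",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw per-subject period-mean features at given group moments.

    Subject 24-h means come from the group Normal (mean, between-subject
    SD).  When a `period` (``day``/``night``/``hour_02_03``) is given,
    the group circadian profiles shift each subject's mean by the
    profile curve averaged over that period — at night both groups drop,
    controls further than patients because of the patients' reduced
    amplitude.  `within_sd_frac` optionally adds a within-subject
    averaging error; the default is 0 since period means average many
    windows over several days and the generator assumes no day-to-day
    variance.  Returns columns ``subject_id, group, log_hr, log_rmssd``.
    """
    from .features import PERIODS

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _offsets(profile: CircadianProfile) -> tuple[float, float]:
        if period is None:
            return 0.0, 0.0
        lo, hi = PERIODS[period]
        t = np.linspace(lo, hi, 200)
        return (
            float(np.mean(profile.hr_at(t)) - profile.mesor_hr),
            float(np.mean(profile.rmssd_at(t)) - profile.rmssd_level),
        )

    off_c, off_p = _offsets(CONTROL_PROFILE), _offsets(PATIENT_PROFILE)
    rows = []
    for i in range(n_controls + n_patients):
        is_pat = i >= n_controls
        hr_m, hr_sd = hr_patient if is_pat else hr_control
        rm_m, rm_sd = rmssd_patient if is_pat else rmssd_control
        hr_off, rm_off = off_p if is_pat else off_c
        hr = max(rng.normal(hr_m, hr_sd) + hr_off, 35.0)
        rm = max(rng.normal(rm_m, rm_sd) + rm_off, 5.0)
        hr *= 1 + within_sd_frac * rng.standard_normal()
        rm *= 1 + within_sd_frac * rng.standard_normal()
        rows.append({"subject_id": f"S{i:03d}", "group": int(is_pat),
                     "log_hr": float(np.log(hr)), "log_rmssd": float(np.log(rm))})
    return pd.DataFrame(rows)
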