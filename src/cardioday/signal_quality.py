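"""Beat detection and per-segment ECG quality indication.

Every 10-s segment of a recording receives a binary quality indicator
(QI).  A segment is good (1) only if it passes, in order:

1. three beat-plausibility rules on the RR intervals detected inside the
   segment — (a) mean heart rate within a physiologically plausible
   range (40–180 bpm), (b) no RR interval longer than 3 s, and (c) a
   max/min RR ratio no larger than 2.2;
2. adaptive QRS template matching: each detected beat is correlated with
   a running average beat shape, and the segment passes when the mean
   correlation reaches a threshold (default 0.66).

Template matching is only evaluated when all three rules pass, so a
segment failing step 1 never updates the running template.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d
from scipy.signal import butter, find_peaks, sosfiltfilt

__all__ = [
    "BeatSeries",
    "QualitySegment",
    "RuleFlags",
    "TemplateMatcher",
    "detect_beats",
    "rule_check",
    "compute_qi",
]

SEGMENT_S = 10.0
HR_RANGE_BPM = (40.0, 180.0)
MAX_RR_MS = 3000.0
MAX_RR_RATIO = 2.2
REFRACTORY_S = 0.25


@dataclass(frozen=True)
class BeatSeries:
    """Beat timestamps (seconds since recording start) for one recording.

    RR intervals are derived, in milliseconds:
    ``rr[i] = 1000 * (beat_times[i+1] - beat_times[i])``.
    """

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.beat_times, dtype=float)
        object.__setattr__(self, "beat_times", t)
        if t.ndim != 1:
            raise ValueError("beat_times must be one-dimensional")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("beat_times must be strictly increasing")

    @property
    def rr(self) -> np.ndarray:
        """Successive RR intervals in milliseconds."""
        return 1000.0 * np.diff(self.beat_times)

    def __len__(self) -> int:
        return int(self.beat_times.size)

    def segment_rr(self, start: float, stop: float) -> np.ndarray:
        """RR intervals whose defining beat pair lies fully in [start, stop)."""
        t = self.beat_times
        lo = int(np.searchsorted(t, start, side="left"))
        hi = int(np.searchsorted(t, stop, side="left"))
        if hi - lo < 2:
            return np.empty(0)
        return 1000.0 * np.diff(t[lo:hi])


@dataclass(frozen=True)
class RuleFlags:
    hr_range: bool
    rr_gap: bool
    rr_ratio: bool
    template: bool = False

    def rules_pass(self) -> bool:
        return self.hr_range and self.rr_gap and self.rr_ratio

    def all_pass(self) -> bool:
        return self.rules_pass() and self.template


@dataclass(frozen=True)
class QualitySegment:
    """One 10-s segment with its binary quality indicator and diagnostics."""

    start: float
    qi: int
    flags: RuleFlags
    duration: float = SEGMENT_S


def detect_beats(ecg: np.ndarray, fs: float) -> BeatSeries:
    """Detect QRS complexes with a Pan–Tompkins-style detector.

    Band-pass (5–18 Hz), differentiate, square, and integrate over a
    150-ms moving window; peaks of the integrated signal above a locally
    adaptive threshold mark candidate beats, which are then refined to
    the nearest extremum of the band-passed signal.  The threshold is a
    fixed fraction of the local signal envelope with a global noise
    floor, so detection is invariant to overall gain.  A 250-ms
    refractory period is enforced.

    Parameters
    ----------
    ecg : array
        Single-lead ECG samples.
    fs : float
        Sampling rate in Hz (>= 128).

    Returns
    -------
    BeatSeries
        Beat times in seconds; empty for a flat signal.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 128:
        raise ValueError(f"sampling rate {fs} Hz too low; need >= 128 Hz")
    if ecg.size < 2 * fs:
        raise ValueError("signal shorter than 2 s")
    if np.ptp(ecg) == 0:
        return BeatSeries(np.empty(0))

    sos = butter(2, [5.0, 18.0], btype="band", fs=fs, output="sos")
    filt = sosfiltfilt(sos, ecg)
    sq = np.gradient(filt) ** 2
    win = max(int(round(0.15 * fs)), 1)
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    # locally adaptive threshold: fraction of the 2.5-s envelope,
    # floored globally so noise-only stretches yield no beats
    envelope = maximum_filter1d(integ, size=int(round(2.5 * fs)))
    floor = 8.0 * np.median(integ)
    height = np.maximum(0.3 * envelope, floor)
    if np.max(integ) <= 0:
        return BeatSeries(np.empty(0))
    peaks, _ = find_peaks(integ, height=height, distance=int(round(REFRACTORY_S * fs)))

    # refine each candidate to the sharpest deflection of the band-passed
    # signal within +-80 ms
    half = int(round(0.08 * fs))
    refined = np.empty(peaks.size, dtype=np.int64)
    absf = np.abs(filt)
    for i, p in enumerate(peaks):
        lo, hi = max(p - half, 0), min(p + half + 1, absf.size)
        refined[i] = lo + int(np.argmax(absf[lo:hi]))
    refined = np.unique(refined)
    if refined.size > 1:  # re-enforce refractory after refinement
        keep = [0]
        for i in range(1, refined.size):
            if refined[i] - refined[keep[-1]] >= REFRACTORY_S * fs:
                keep.append(i)
        refined = refined[keep]
    return BeatSeries(refined / fs)


def rule_check(segment_rr: np.ndarray) -> RuleFlags:
    """Apply the three RR-plausibility rules to one 10-s segment.

    ``segment_rr`` holds the RR intervals (ms) whose beat pairs lie fully
    inside the segment.  Fewer than two beats in the segment (no RR at
    all) fails every rule.
    """
    rr = np.asarray(segment_rr, dtype=float)
    if rr.size == 0:
        return RuleFlags(False, False, False)
    mean_hr = 60000.0 / np.mean(rr)
    hr_ok = HR_RANGE_BPM[0] <= mean_hr <= HR_RANGE_BPM[1]
    gap_ok = float(np.max(rr)) <= MAX_RR_MS
    ratio_ok = float(np.max(rr)) / float(np.min(rr)) <= MAX_RR_RATIO
    return RuleFlags(hr_ok, gap_ok, ratio_ok)


@dataclass
class TemplateMatcher:
    """Adaptive QRS template state shared across consecutive segments.

    The template is the exponentially averaged mean beat of passing
    segments; beats are extracted in a window of +-`beat_window_frac`
    times the segment median RR around each detected beat.  After
    `reset_after` consecutive failing segments the template is dropped
    and re-initialised from the next segment's own mean beat.
    """

    threshold: float = 0.66
    alpha: float = 0.1
    beat_window_frac: float = 0.35
    reset_after: int = 5
    template: np.ndarray | None = field(default=None, repr=False)
    _fail_streak: int = field(default=0, repr=False)

    def match(self, ecg_segment: np.ndarray, beat_idx: np.ndarray, fs: float) -> bool:
        """Correlate the segment's beats with the running template.

        Returns True (pass) when the mean Pearson correlation reaches
        the threshold; updates the adaptive template on pass.
        """
        ecg_segment = np.asarray(ecg_segment, dtype=float)
        beat_idx = np.asarray(beat_idx, dtype=np.int64)
        if beat_idx.size < 2:
            return self._fail()
        med_rr_s = float(np.median(np.diff(beat_idx))) / fs
        half = max(int(round(self.beat_window_frac * med_rr_s * fs)), 2)
        windows = []
        for b in beat_idx:
            if b - half < 0 or b + half + 1 > ecg_segment.size:
                continue
            windows.append(ecg_segment[b - half : b + half + 1])
        if len(windows) < 2:
            return self._fail()
        windows = np.asarray(windows)
        mean_beat = windows.mean(axis=0)
        if self.template is None:
            reference = mean_beat  # self-similarity on first use
        else:
            reference = _resample(self.template, windows.shape[1])
        corrs = np.array([_pearson(w, reference) for w in windows])
        passed = bool(np.mean(corrs) >= self.threshold)
        if passed:
            if self.template is None:
                self.template = mean_beat
            else:
                old = _resample(self.template, mean_beat.size)
                self.template = (1 - self.alpha) * old + self.alpha * mean_beat
            self._fail_streak = 0
        else:
            self._fail()
        return passed

    def _fail(self) -> bool:
        self._fail_streak += 1
        if self._fail_streak >= self.reset_after:
            self.template = None
            self._fail_streak = 0
        return False


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _resample(x: np.ndarray, n: int) -> np.ndarray:
    if x.size == n:
        return x
    return np.interp(np.linspace(0, 1, n), np.linspace(0, 1, x.size), x)


def compute_qi(
    ecg: np.ndarray,
    fs: float,
    beats: BeatSeries | None = None,
    matcher: TemplateMatcher | None = None,
) -> list[QualitySegment]:
    """Label every contiguous 10-s segment of a recording 0/1.

    Beats are detected once over the whole recording (or supplied), then
    each segment is checked with the two-step rule/template procedure.
    The template step runs only on segments passing all three rules.
    """
    ecg = np.asarray(ecg, dtype=float)
    n_seg = int(ecg.size // (SEGMENT_S * fs))
    if n_seg == 0:
        return []
    if beats is None:
        beats = detect_beats(ecg, fs)
    matcher = matcher if matcher is not None else TemplateMatcher()
    out: list[QualitySegment] = []
    for k in range(n_seg):
        start = k * SEGMENT_S
        rr = beats.segment_rr(start, start + SEGMENT_S)
        flags = rule_check(rr)
        template_ok = False
        if flags.rules_pass():
            i0 = int(start * fs)
            inside = (beats.beat_times >= start) & (beats.beat_times < start + SEGMENT_S)
            idx = np.round(beats.beat_times[inside] * fs).astype(np.int64) - i0
            seg = ecg[i0 : i0 + int(SEGMENT_S * fs)]
            template_ok = matcher.match(seg, idx, fs)
        flags = RuleFlags(flags.hr_range, flags.rr_gap, flags.rr_ratio, template_ok)
        out.append(QualitySegment(start=start, qi=int(flags.all_pass()), flags=flags))
    return out
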