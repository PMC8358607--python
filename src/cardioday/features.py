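"""Windowed HR/RMSSD/activity features, filtering, and aggregation.

Features are computed in 5-min windows with 4-min overlap (a new window
every 60 s).  A window is retained for analysis only when its mean
quality indicator is at least 0.8 and its acceleration-magnitude SD does
not exceed 0.04 g; retained windows are then averaged per subject into
clock-hour (or coarser) bins across all recording days and
log-transformed.

Boundary semantics follow the strict inequalities of the filtering
rules: a window at mean QI exactly 0.8 or std ACC exactly 0.04 is
retained.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signal_quality import BeatSeries, QualitySegment

__all__ = [
    "window_retained",
    "rmssd",
    "mean_hr",
    "acc_magnitude",
    "std_acc",
    "windowize",
    "aggregate",
    "overall_activity_index",
    "PERIODS",
]

WINDOW_S = 300.0
STEP_S = 60.0
QI_THRESHOLD = 0.8
ACC_THRESHOLD = 0.04

#: named clock-hour periods used for classification and covariate checks
PERIODS: dict[str, tuple[int, int]] = {
    "day": (12, 18),  # 12:00-18:00
    "night": (0, 6),  # 00:00-06:00
    "hour_02_03": (2, 3),  # hour block 2
}


def window_retained(
    mean_qi: float,
    sd_acc: float,
    qi_threshold: float = QI_THRESHOLD,
    acc_threshold: float = ACC_THRESHOLD,
) -> bool:
    """Retention rule for one 5-min window.

    Windows with average QI *below* 0.8 are excluded and windows with
    std ACC *above* 0.04 g are excluded — both strict, so a window at
    exactly 0.8 / 0.04 is retained.  A missing (NaN) std ACC does not
    exclude.
    """
    return bool(mean_qi >= qi_threshold and not (sd_acc > acc_threshold))


def rmssd(rr: np.ndarray) -> float:
    """Root mean square of successive RR differences, in ms.

    Requires at least two RR intervals (three beats); returns NaN
    otherwise so the caller can flag the window.
    """
    rr = np.asarray(rr, dtype=float)
    if rr.size < 2:
        return float("nan")
    return float(np.sqrt(np.mean(np.diff(rr) ** 2)))


def mean_hr(rr: np.ndarray) -> float:
    """Mean heart rate in bpm, defined as 60000 / mean(RR in ms)."""
    rr = np.asarray(rr, dtype=float)
    if rr.size < 1:
        return float("nan")
    return float(60000.0 / np.mean(rr))


def acc_magnitude(acc: np.ndarray) -> np.ndarray:
    """Euclidean magnitude of a 3-axis acceleration array (n, 3)."""
    acc = np.asarray(acc, dtype=float)
    if acc.ndim == 1:
        return np.abs(acc)
    return np.sqrt(np.sum(acc**2, axis=1))


def std_acc(acc_window: np.ndarray) -> float:
    """SD of the acceleration magnitude over one window (g-units)."""
    mag = acc_magnitude(acc_window)
    if mag.size == 0:
        return float("nan")
    return float(np.std(mag))


def overall_activity_index(acc: np.ndarray) -> float:
    """General activity index: SD of acceleration magnitude over the
    entire recording, with no high-activity filtering."""
    return std_acc(acc)


def windowize(
    beats: BeatSeries,
    acc: np.ndarray | None = None,
    acc_fs: float | None = None,
    qi_segments: list[QualitySegment] | None = None,
    duration: float | None = None,
    subject_id: str = "",
    window: float = WINDOW_S,
    step: float = STEP_S,
    qi_threshold: float = QI_THRESHOLD,
    acc_threshold: float = ACC_THRESHOLD,
) -> pd.DataFrame:
    """Compute overlapping feature windows over one recording.

    Windows start every `step` seconds and span `window` seconds.  A
    window's RR set contains every interval whose defining beat pair
    lies fully inside the window.  The window's mean QI averages the QI
    of all 10-s segments overlapping it (1.0 when no QI is supplied).

    Returns a DataFrame with one row per window: ``subject_id,
    window_start, mean_hr, rmssd, mean_qi, std_acc, retained``.
    Windows without enough beats get NaN features and are never
    retained.
    """
    if duration is None:
        if len(beats) > 0:
            duration = float(beats.beat_times[-1])
        elif acc is not None and acc_fs:
            duration = len(acc) / acc_fs
        else:
            duration = 0.0
    starts = np.arange(0.0, duration - window + 1e-9, step)

    qi_starts = qi_vals = None
    if qi_segments:
        qi_starts = np.array([s.start for s in qi_segments])
        qi_vals = np.array([s.qi for s in qi_segments], dtype=float)
        qi_dur = qi_segments[0].duration
    mag = acc_magnitude(acc) if acc is not None else None

    rows = []
    for w0 in starts:
        w1 = w0 + window
        rr = beats.segment_rr(w0, w1)
        hr = mean_hr(rr)
        rm = rmssd(rr)
        if qi_vals is not None:
            lo = int(np.searchsorted(qi_starts, w0 - qi_dur, side="right"))
            hi = int(np.searchsorted(qi_starts, w1, side="left"))
            mean_qi = float(np.mean(qi_vals[lo:hi])) if hi > lo else 0.0
        else:
            mean_qi = 1.0
        if mag is not None and acc_fs:
            i0, i1 = int(w0 * acc_fs), int(w1 * acc_fs)
            sd_acc = float(np.std(mag[i0:i1])) if i1 <= mag.size and i1 > i0 else float("nan")
        else:
            sd_acc = float("nan")
        retained = (
            window_retained(mean_qi, sd_acc, qi_threshold, acc_threshold)
            and np.isfinite(hr)
            and np.isfinite(rm)
        )
        rows.append((subject_id, w0, hr, rm, mean_qi, sd_acc, bool(retained)))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "window_start", "mean_hr", "rmssd", "mean_qi", "std_acc", "retained"],
    )


def aggregate(
    windows: pd.DataFrame,
    start_hour: float = 0.0,
    level: str = "hour",
    phase: str = "pre",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average retained windows into clock-time bins and log-transform.

    Parameters
    ----------
    windows : DataFrame
        Output of :func:`windowize` (possibly several subjects).
    start_hour : float
        Local clock hour at recording start; each window's clock hour is
        derived from its start time.
    level : str
        ``hour`` (0-23), ``block6`` (0-3), or a named period from
        :data:`PERIODS` (``day``, ``night``, ``hour_02_03``).
    phase : str
        Recording phase label carried through (``pre``/``post``).

    Returns
    -------
    (records, coverage)
        `records` has one row per subject x bin with ``log_hr``,
        ``log_rmssd`` and ``n_windows``; bins with no retained window
        are omitted and listed in `coverage`.
    """
    w = windows.copy()
    w["clock_hour"] = np.floor((start_hour + w["window_start"] / 3600.0) % 24).astype(int)
    if level == "hour":
        w["bin"] = w["clock_hour"]
        all_bins = list(range(24))
    elif level == "block6":
        w["bin"] = w["clock_hour"] // 6
        all_bins = list(range(4))
    elif level in PERIODS:
        lo, hi = PERIODS[level]
        w = w[(w["clock_hour"] >= lo) & (w["clock_hour"] < hi)]
        w["bin"] = level
        all_bins = [level]
    else:
        raise ValueError(f"unknown aggregation level {level!r}")

    retained = w[w["retained"]]
    grouped = (
        retained.groupby(["subject_id", "bin"])
        .agg(mean_hr=("mean_hr", "mean"), mean_rmssd=("rmssd", "mean"), n_windows=("retained", "size"))
        .reset_index()
    )
    grouped["log_hr"] = np.log(grouped["mean_hr"])
    grouped["log_rmssd"] = np.log(grouped["mean_rmssd"])
    grouped["phase"] = phase
    records = grouped[["subject_id", "bin", "log_hr", "log_rmssd", "n_windows", "phase"]]

    missing = []
    for sid in w["subject_id"].unique():
        have = set(records.loc[records["subject_id"] == sid, "bin"])
        for b in all_bins:
            if b not in have:
                missing.append((sid, b))
    coverage = pd.DataFrame(missing, columns=["subject_id", "bin"])
    return records.reset_index(drop=True), coverage
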