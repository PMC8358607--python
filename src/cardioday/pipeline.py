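"""End-to-end glue: simulated or measured recordings -> model-ready tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import PERIODS, aggregate, overall_activity_index, windowize
from .io_formats import SubjectMeta
from .synthetic_data import SubjectRecording

__all__ = [
    "recording_windows",
    "cohort_hourly",
    "cohort_period_features",
    "meta_frame",
]


def recording_windows(rec: SubjectRecording, qi_segments=None) -> pd.DataFrame:
    """Feature windows for one in-memory recording."""
    duration = float(rec.beats.beat_times[-1]) if len(rec.beats) else 0.0
    return windowize(
        rec.beats,
        acc=rec.acc,
        acc_fs=rec.acc_fs,
        qi_segments=qi_segments,
        duration=duration,
        subject_id=rec.meta.subject_id,
    )


def cohort_hourly(recordings: list[SubjectRecording], level: str = "hour") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Windowize and aggregate every recording; returns (records, coverage).

    Recordings are processed one at a time so full cohorts stay within
    memory; the phase label of each recording is carried through.
    """
    parts, cov_parts = [], []
    for rec in recordings:
        w = recording_windows(rec)
        r, cov = aggregate(w, start_hour=rec.start_hour, level=level, phase=rec.phase)
        parts.append(r)
        cov_parts.append(cov)
    records = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame()
    coverage = pd.concat(cov_parts, ignore_index=True) if cov_parts else pd.DataFrame()
    return records, coverage


def cohort_period_features(recordings: list[SubjectRecording]) -> dict[str, pd.DataFrame]:
    """Per-subject period means (day / night / hour 2-3) for classification."""
    out: dict[str, pd.DataFrame] = {}
    pre = [r for r in recordings if r.phase == "pre"]
    for period in PERIODS:
        rows = []
        for rec in pre:
            w = recording_windows(rec)
            r, _ = aggregate(w, start_hour=rec.start_hour, level=period, phase=rec.phase)
            if len(r):
                rows.append(
                    {
                        "subject_id": rec.meta.subject_id,
                        "group": int(rec.meta.group == "patient"),
                        "log_hr": float(r["log_hr"].iloc[0]),
                        "log_rmssd": float(r["log_rmssd"].iloc[0]),
                    }
                )
        out[period] = pd.DataFrame(rows)
    return out


def meta_frame(metas: list[SubjectMeta], recordings: list[SubjectRecording] | None = None) -> pd.DataFrame:
    """Subject metadata table, with the overall activity index when ACC exists."""
    act = {}
    for rec in recordings or []:
        if rec.acc is not None and rec.phase == "pre":
            act[rec.meta.subject_id] = overall_activity_index(rec.acc)
    rows = []
    for m in metas:
        rows.append(
            {
                "subject_id": m.subject_id, "group": m.group, "age": m.age, "sex": m.sex,
                "bmi": m.bmi, "hrsd_baseline": m.hrsd_baseline, "hrsd_24h_post": m.hrsd_24h_post,
                "arm": m.arm, "smoker": m.smoker, "sleep_quality": m.sleep_quality,
                "activity": act.get(m.subject_id, np.nan),
            }
        )
    return pd.DataFrame(rows)
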