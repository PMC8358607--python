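"""On-disk formats: recordings (EDF/CSV), feature and metadata tables, config.

Canonical internal time is seconds since recording start; the local
clock hour is derived from the bundle's ``start_time`` (no DST
adjustment within one recording).  All CSV output uses comma separators,
'.' decimals, ISO-8601 timestamps and UTF-8.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RecordingBundle",
    "SubjectMeta",
    "read_recording",
    "write_recording_csv",
    "write_feature_table",
    "read_feature_table",
    "write_meta_table",
    "read_meta_table",
    "load_config",
]

FEATURE_COLUMNS = ["subject_id", "window_start", "mean_hr", "rmssd", "mean_qi", "std_acc", "retained"]
_FLOAT_FMT = "%.6f"


class FormatError(RuntimeError):
    """Unreadable or structurally invalid input file."""


class MetadataError(RuntimeError):
    """Required metadata (sampling rate, start time, ...) missing."""


@dataclass
class RecordingBundle:
    """Raw signals of one subject-recording.

    ECG in volts at `ecg_fs` Hz; 3-axis acceleration in g-units at
    `acc_fs` Hz; `start_time` fixes the local clock hour of sample 0.
    """

    subject_id: str
    ecg: np.ndarray
    ecg_fs: float
    acc: np.ndarray | None = None
    acc_fs: float | None = None
    start_time: datetime | None = None

    def __post_init__(self) -> None:
        if self.ecg_fs <= 0:
            raise MetadataError("ECG sampling rate must be positive")
        if self.acc is not None and (self.acc_fs is None or self.acc_fs <= 0):
            raise MetadataError("ACC present but its sampling rate is missing")
        if np.size(self.ecg) == 0:
            raise MetadataError("zero-length ECG signal")

    @property
    def start_hour(self) -> float:
        """Local clock hour (fractional) at recording start; 0.0 if unset."""
        if self.start_time is None:
            return 0.0
        t = self.start_time
        return t.hour + t.minute / 60.0 + t.second / 3600.0

    @property
    def duration(self) -> float:
        return np.size(self.ecg) / self.ecg_fs


@dataclass
class SubjectMeta:
    """Clinical metadata for one subject."""

    subject_id: str
    group: str  # control | patient
    age: float
    sex: str  # female | male
    bmi: float
    hrsd_baseline: int
    hrsd_24h_post: int | None = None
    arm: str = "none"  # ketamine | placebo | none
    phase: str = "pre"
    smoker: bool = False
    sleep_quality: bool | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in {"control", "patient"}:
            raise ValueError(f"unknown group {self.group!r}")
        if self.hrsd_baseline < 0:
            raise ValueError("HRSD scores must be non-negative")
        if (self.arm == "none") != (self.group == "control"):
            raise ValueError("arm='none' exactly for controls")


def read_recording(path: str | Path, format: str | None = None) -> RecordingBundle:
    """Read a raw recording from EDF or CSV into a :class:`RecordingBundle`.

    For CSV, `path` points at a table with columns ``t, ecg`` (and
    optionally ``acc_x, acc_y, acc_z`` in a sibling ``<stem>_acc.csv``);
    sampling rate is taken from the sidecar ``<stem>.json`` if present,
    otherwise inferred from the time column.  Gaps are preserved as NaN
    samples, never interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        return _read_edf(path)
    if fmt == "csv":
        return _read_csv_recording(path)
    raise FormatError(f"unknown recording format {fmt!r}")


def _read_edf(path: Path) -> RecordingBundle:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise FormatError(f"cannot read EDF {path}: {exc}") from exc
    if raw.info["sfreq"] <= 0:
        raise MetadataError("EDF missing sampling rate")
    names = raw.ch_names
    ecg_ch = next((c for c in names if "ecg" in c.lower()), names[0])
    ecg = raw.get_data(picks=[ecg_ch])[0]
    acc_chs = [c for c in names if c.lower().startswith("acc")]
    acc = raw.get_data(picks=acc_chs).T if len(acc_chs) == 3 else None
    meas = raw.info.get("meas_date")
    start = meas.replace(tzinfo=None) if meas is not None else None
    return RecordingBundle(
        subject_id=path.stem,
        ecg=ecg,
        ecg_fs=float(raw.info["sfreq"]),
        acc=acc,
        acc_fs=float(raw.info["sfreq"]) if acc is not None else None,
        start_time=start,
    )


def _read_csv_recording(path: Path) -> RecordingBundle:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot read CSV {path}: {exc}") from exc
    if "ecg" not in df.columns:
        raise FormatError(f"{path} has no 'ecg' column")
    if len(df) == 0:
        raise MetadataError("zero-length ECG signal")

    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if "ecg_fs" in meta:
        fs = float(meta["ecg_fs"])
    elif "t" in df.columns and len(df) > 1:
        fs = 1.0 / float(np.median(np.diff(df["t"].to_numpy())))
    else:
        raise MetadataError(f"{path}: sampling rate not declared and not inferable")

    acc = acc_fs = None
    acc_path = path.with_name(path.stem + "_acc.csv")
    if acc_path.exists():
        adf = pd.read_csv(acc_path)
        acc = adf[["acc_x", "acc_y", "acc_z"]].to_numpy()
        if "acc_fs" in meta:
            acc_fs = float(meta["acc_fs"])
        elif "t" in adf.columns and len(adf) > 1:
            acc_fs = 1.0 / float(np.median(np.diff(adf["t"].to_numpy())))
        else:
            raise MetadataError(f"{acc_path}: ACC sampling rate not declared")

    start = datetime.fromisoformat(meta["start_time"]) if "start_time" in meta else None
    return RecordingBundle(
        subject_id=meta.get("subject_id", path.stem),
        ecg=df["ecg"].to_numpy(dtype=float),
        ecg_fs=fs,
        acc=acc,
        acc_fs=acc_fs,
        start_time=start,
    )


def write_recording_csv(bundle: RecordingBundle, stem: str | Path) -> Path:
    """Write a bundle as ``<stem>.csv`` (+ ``_acc.csv``, ``.json`` sidecar)."""
    stem = Path(stem)
    t = np.arange(np.size(bundle.ecg)) / bundle.ecg_fs
    pd.DataFrame({"t": t, "ecg": bundle.ecg}).to_csv(
        stem.with_suffix(".csv"), index=False, float_format=_FLOAT_FMT
    )
    meta: dict = {"subject_id": bundle.subject_id, "ecg_fs": bundle.ecg_fs}
    if bundle.acc is not None:
        ta = np.arange(len(bundle.acc)) / bundle.acc_fs
        pd.DataFrame(
            {"t": ta, "acc_x": bundle.acc[:, 0], "acc_y": bundle.acc[:, 1], "acc_z": bundle.acc[:, 2]}
        ).to_csv(stem.parent / (stem.name + "_acc.csv"), index=False, float_format=_FLOAT_FMT)
        meta["acc_fs"] = bundle.acc_fs
    if bundle.start_time is not None:
        meta["start_time"] = bundle.start_time.isoformat()
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return stem.with_suffix(".csv")


def write_feature_table(windows: pd.DataFrame, path: str | Path) -> Path:
    """Write feature windows to CSV; round-trips losslessly at 6 decimals."""
    if len(windows) == 0:
        raise ValueError("refusing to write an empty feature table")
    path = Path(path)
    out = windows[FEATURE_COLUMNS].copy()
    for c in ["window_start", "mean_hr", "rmssd", "mean_qi", "std_acc"]:
        out[c] = out[c].round(6)
    out.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"feature table {path} missing columns {sorted(missing)}")
    df["retained"] = df["retained"].astype(bool)
    return df[FEATURE_COLUMNS]


def write_meta_table(metas: list[SubjectMeta], path: str | Path) -> Path:
    rows = []
    for m in metas:
        rows.append(
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "age": m.age,
                "sex": m.sex,
                "bmi": m.bmi,
                "hrsd_baseline": m.hrsd_baseline,
                "hrsd_24h_post": m.hrsd_24h_post,
                "arm": m.arm,
                "phase": m.phase,
                "smoker": m.smoker,
                "sleep_quality": m.sleep_quality,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_meta_table(path: str | Path) -> list[SubjectMeta]:
    df = pd.read_csv(path)
    metas = []
    for _, r in df.iterrows():
        post = r.get("hrsd_24h_post")
        metas.append(
            SubjectMeta(
                subject_id=str(r["subject_id"]),
                group=str(r["group"]),
                age=float(r["age"]),
                sex=str(r["sex"]),
                bmi=float(r["bmi"]),
                hrsd_baseline=int(r["hrsd_baseline"]),
                hrsd_24h_post=None if pd.isna(post) else int(post),
                arm=str(r.get("arm", "none")),
                phase=str(r.get("phase", "pre")),
                smoker=bool(r.get("smoker", False)),
                sleep_quality=None if pd.isna(r.get("sleep_quality")) else bool(r.get("sleep_quality")),
            )
        )
    return metas


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Load a YAML/JSON config; CLI overrides take precedence over the file,
    which takes precedence over library defaults."""
    cfg: dict = {}
    if path is not None:
        text = Path(path).read_text()
        cfg = yaml.safe_load(text) or {}
        if not isinstance(cfg, dict):
            raise FormatError(f"config {path} is not a mapping")
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg
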