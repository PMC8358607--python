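"""Shared fixtures: synthetic recordings and a minimal EDF writer.

No EDF-writing library is available, so the EDF fixture below writes the
format's plain 256-byte ASCII header plus int16 samples by hand; it
exists only to exercise the EDF *reading* path and is not part of the
package.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from cardioday.signal_quality import BeatSeries
from cardioday.synthetic_data import CircadianProfile, render_ecg, simulate_beat_series


@pytest.fixture(scope="session")
def steady_profile() -> CircadianProfile:
    """Flat 60-bpm profile with moderate beat-to-beat variability."""
    return CircadianProfile(mesor_hr=60.0, rmssd_level=30.0)


@pytest.fixture(scope="session")
def clean_ecg_10min() -> tuple[np.ndarray, float, BeatSeries]:
    """10 minutes of artifact-free synthetic ECG at 256 Hz with truth beats."""
    profile = CircadianProfile(mesor_hr=70.0, rmssd_level=40.0)
    beats = simulate_beat_series(profile, days=1, seed=101)
    short = BeatSeries(beats.beat_times[beats.beat_times < 600.0])
    ecg = render_ecg(short, fs=256.0, seed=102, duration=600.0)
    return ecg, 256.0, short


def write_minimal_edf(path: Path, signal: np.ndarray, fs: int, label: str = "ECG") -> Path:
    """Write a single-channel EDF file (synthetic test fixture).

    1-s data records; physical range +-2.0 units mapped onto the full
    int16 digital range.
    """
    n_rec = int(len(signal) // fs)
    signal = np.asarray(signal[: n_rec * fs], dtype=float)
    phys_min, phys_max = -2.0, 2.0
    dig_min, dig_max = -32768, 32767
    scaled = np.clip((signal - phys_min) / (phys_max - phys_min), 0, 1)
    digital = (scaled * (dig_max - dig_min) + dig_min).astype("<i2")

    def pad(s: str, n: int) -> bytes:
        return s.ljust(n)[:n].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("X X X X", 80),
            pad("Startdate 01-JAN-2024 X X X", 80),
            pad("01.01.24", 8),
            pad("00.00.00", 8),
            pad(str(256 * 2), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad("1", 8),
            pad("1", 4),
            # per-signal header fields
            pad(label, 16),
            pad("", 80),
            pad("mV", 8),
            pad(str(phys_min), 8),
            pad(str(phys_max), 8),
            pad(str(dig_min), 8),
            pad(str(dig_max), 8),
            pad("", 80),
            pad(str(fs), 8),
            pad("", 32),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())
    return path
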