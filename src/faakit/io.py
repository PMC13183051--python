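"""On-disk formats: EEG channel matrices (CSV + JSON sidecar, EDF) and
cohort CSV files.

The CSV dialect is one column per channel (header row of 10-20 labels), one
sample per row, with the sampling rate in ``<stem>.json``. EDF output is a
minimal single-record EDF writer (16-bit, physical scaling from the data
range); EDF input goes through MNE's reader, which also serves as an
independent check of the writer in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EEGRecording
from .synthetic import PatientRecord

COHORT_COLUMNS = [
    "subject_id", "age_yr", "sex", "bmi", "se_duration_gt60",
    "epilepsy_history", "seizure_type", "time_to_cessation_gt30", "picu_days",
    "faa_e3", "underlying_disease", "respiratory_failure", "vasopressor_use",
    "gfap_pre", "gfap_post", "s100b_pre", "s100b_post", "gaba_pre",
    "gaba_post", "gos_level",
]


# ---------------------------------------------------------------- EEG CSV --

def write_eeg_csv(rec: EEGRecording, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(rec.samples.T, columns=rec.channel_labels)
    df.to_csv(path, index=False, float_format="%.6f")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"fs_hz": rec.fs,
                                   "channels": rec.channel_labels}, indent=2))
    return path


def read_eeg_csv(path: str | Path) -> EEGRecording:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"sampling-rate sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    return EEGRecording(samples=df.to_numpy(dtype=float).T, fs=float(meta["fs_hz"]),
                        channel_labels=[str(c) for c in df.columns])


# -------------------------------------------------------------------- EDF --

def _fit8(v: float) -> str:
    """Densest ASCII rendering of ``v`` that fits EDF's 8-char numeric field."""
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def write_edf(rec: EEGRecording, path: str | Path,
              record_duration_s: float = 1.0) -> Path:
    """Write a plain 16-bit EDF file (one data record per second by default).

    Physical min/max come from each channel's data range, so quantization
    error is at most range/(2^16-1)/2 per sample. The tail is zero-padded to
    a whole number of records; readers recover the true length from the
    stored record count times duration.
    """
    path = Path(path)
    n_ch = rec.n_channels
    spr = int(round(record_duration_s * rec.fs))  # samples per record/channel
    n_rec = int(np.ceil(rec.n_samples / spr))

    def f(text: str, width: int) -> bytes:
        s = str(text)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        f("0", 8), f("X X X X", 80), f("X X X", 80),
        f("01.01.00", 8), f("00.00.00", 8),
        f(str(256 * (n_ch + 1)), 8), f("", 44),
        f(str(n_rec), 8), f(f"{record_duration_s:g}", 8), f(str(n_ch), 4),
    ])
    phys_min, phys_max, scales, offsets = [], [], [], []
    for ch in range(n_ch):
        lo = float(np.min(rec.samples[ch]))
        hi = float(np.max(rec.samples[ch]))
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scales.append((hi - lo) / (32767 - (-32768)))
        offsets.append(lo)
    sig_header = b"".join([
        b"".join(f(lbl, 16) for lbl in rec.channel_labels),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f("uV", 8) for _ in range(n_ch)),
        b"".join(f(_fit8(phys_min[c]), 8) for c in range(n_ch)),
        b"".join(f(_fit8(phys_max[c]), 8) for c in range(n_ch)),
        b"".join(f("-32768", 8) for _ in range(n_ch)),
        b"".join(f("32767", 8) for _ in range(n_ch)),
        b"".join(f("", 80) for _ in range(n_ch)),
        b"".join(f(str(spr), 8) for _ in range(n_ch)),
        b"".join(f("", 32) for _ in range(n_ch)),
    ])

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :rec.n_samples] = rec.samples
    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for ch in range(n_ch):
                seg = padded[ch, r * spr:(r + 1) * spr]
                lo, hi = phys_min[ch], phys_max[ch]
                dig = np.round((seg - lo) / (hi - lo) * 65535.0 - 32768.0)
                fh.write(np.clip(dig, -32768, 32767).astype("<i2").tobytes())
    return path


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF file via MNE; amplitudes converted back to microvolts."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(samples=data, fs=float(raw.info["sfreq"]),
                        channel_labels=list(raw.ch_names))


def read_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    return read_eeg_csv(path)


# ------------------------------------------------------------- cohort CSV --

def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame([asdict(r) for r in records])[COHORT_COLUMNS]
    df.to_csv(path, index=False)
    return path


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Load a cohort table and derive the prognosis label from GOS level."""
    from .stats import dichotomize_gos

    df = pd.read_csv(path)
    missing = [c for c in ("faa_e3", "gos_level") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV lacks required columns: {missing}")
    df["prognosis"] = df["gos_level"].map(dichotomize_gos)
    return df
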