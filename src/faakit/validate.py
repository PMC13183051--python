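"""Schema validation of cohort CSV and EEG input files.

Each check appends a human-readable issue string; an empty list means the
file is usable by the pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

VALID_GOS = {"I", "II", "III", "IV", "V"}
REQUIRED_COHORT_COLUMNS = ["faa_e3", "gos_level"]
REQUIRED_EEG_CHANNELS = ["F3", "F4"]


def validate_cohort_csv(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        return [f"file not found: {path}"]
    issues: list[str] = []
    df = pd.read_csv(path)
    for col in REQUIRED_COHORT_COLUMNS:
        if col not in df.columns:
            issues.append(f"missing column: {col}")
    if "gos_level" in df.columns:
        for i, v in df["gos_level"].items():
            if str(v).strip().upper() not in VALID_GOS:
                issues.append(f"row {i}: gos_level {v!r} outside I-V")
    if "faa_e3" in df.columns:
        bad = df.index[pd.to_numeric(df["faa_e3"], errors="coerce").isna()]
        issues.extend(f"row {i}: faa_e3 is not numeric" for i in bad)
    return issues


def validate_eeg_file(path: str | Path) -> list[str]:
    path = Path(path)
    if not path.exists():
        return [f"file not found: {path}"]
    issues: list[str] = []
    if path.suffix.lower() == ".edf":
        from .io import read_edf
        try:
            rec = read_edf(path)
        except Exception as e:  # unreadable header / truncated records
            return [f"unreadable EDF: {e}"]
        labels = [c.lower() for c in rec.channel_labels]
        issues.extend(f"missing channel: {ch}" for ch in REQUIRED_EEG_CHANNELS
                      if ch.lower() not in labels)
        if rec.fs <= 0:
            issues.append(f"non-positive sampling rate: {rec.fs}")
        return issues

    df = pd.read_csv(path)
    labels = [str(c).lower() for c in df.columns]
    issues.extend(f"missing channel: {ch}" for ch in REQUIRED_EEG_CHANNELS
                  if ch.lower() not in labels)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        issues.append(f"missing sampling-rate sidecar: {sidecar.name}")
    else:
        meta = json.loads(sidecar.read_text())
        fs = float(meta.get("fs_hz", 0))
        if fs <= 0:
            issues.append(f"non-positive sampling rate: {fs}")
    return issues
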