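"""Orchestration: one entry point per analysis mode, each producing a
single JSON-ready report dict plus optional CSV sidecars.

Modes
-----
synth_end_to_end : generate a cohort plus per-subject EEG, run the spectral
    chain to get measured FAA, then the statistical battery and ROC
    analysis on the measured values.
cohort_only : run the statistics and ROC analysis on an existing cohort CSV.
eeg_only : compute FAA for EEG files.
worked_examples : recompute the reference cohort's published statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .eeg import faa_from_recording
from .roc import roc_report, stratify_by_cutoff
from .stats import fit_prognosis_model, univariate_table
from .synthetic import CohortConfig, EEGSynthesisSpec, cohort_to_frame, generate_cohort, generate_eeg
from .worked import run_worked_examples, summarize


@dataclass
class RunConfig:
    mode: str  # synth_end_to_end | cohort_only | eeg_only | worked_examples
    out_dir: str | Path = "faakit_out"
    cohort_csv: str | Path | None = None
    eeg_paths: list = field(default_factory=list)
    seed: int = 0
    n_good: int = 126
    n_poor: int = 51
    eeg_duration_s: float = 60.0
    eeg_params: dict = field(default_factory=dict)
    write_eeg_files: bool = False

    def __post_init__(self) -> None:
        valid = ("synth_end_to_end", "cohort_only", "eeg_only", "worked_examples")
        if self.mode not in valid:
            raise ValueError(f"mode must be one of {valid}, got {self.mode!r}")


def _analyze_cohort(df: pd.DataFrame) -> dict:
    report: dict = {"n": len(df),
                    "n_good": int((df.prognosis == "good").sum()),
                    "n_poor": int((df.prognosis == "poor").sum())}
    uni = univariate_table(df)
    report["univariate"] = uni.reset_index().to_dict(orient="records")
    try:
        fit = fit_prognosis_model(df)
        report["logistic"] = fit.table().reset_index().to_dict(orient="records")
    except ValueError as e:
        report["logistic_error"] = str(e)
    roc = roc_report(df["faa_e3"].to_numpy(), df["prognosis"].to_numpy())
    report["roc"] = roc
    try:
        strat = stratify_by_cutoff(df, roc["cutoff"])
        report["cutoff_stratification"] = {
            "cutoff": strat["cutoff"], "n_le": strat["n_le"], "n_gt": strat["n_gt"],
            "outcome_counts": [list(r) for r in strat["outcome_counts"].counts],
            "outcome_chi2": strat["outcome_test"].statistic,
            "outcome_p": strat["outcome_test"].p,
            "markers": {k: {"t": v["t"], "p": v["p"],
                            "le_mean": v["le_cutoff"].mean, "le_sd": v["le_cutoff"].sd,
                            "gt_mean": v["gt_cutoff"].mean, "gt_sd": v["gt_cutoff"].sd}
                        for k, v in strat["markers"].items()},
        }
    except ValueError as e:
        report["cutoff_stratification_error"] = str(e)
    return report


def run(config: RunConfig) -> dict:
    """Execute the configured mode; returns (and writes) the report dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"mode": config.mode, "seed": config.seed,
                    "params": {"n_good": config.n_good, "n_poor": config.n_poor,
                               "eeg_duration_s": config.eeg_duration_s,
                               **config.eeg_params}}

    if config.mode == "worked_examples":
        report["worked_examples"] = summarize(run_worked_examples())

    elif config.mode == "cohort_only":
        if config.cohort_csv is None:
            raise ValueError("cohort_only mode requires cohort_csv")
        df = fio.read_cohort_csv(config.cohort_csv)
        report["cohort"] = _analyze_cohort(df)

    elif config.mode == "eeg_only":
        if not config.eeg_paths:
            raise ValueError("eeg_only mode requires eeg_paths")
        report["subjects"] = []
        for p in config.eeg_paths:
            rec = fio.read_eeg(p)
            res = faa_from_recording(rec, **config.eeg_params)
            res["file"] = str(p)
            report["subjects"].append(res)

    else:  # synth_end_to_end
        rng = np.random.default_rng(config.seed)
        cohort = generate_cohort(CohortConfig(n_good=config.n_good,
                                              n_poor=config.n_poor,
                                              seed=config.seed))
        df = cohort_to_frame(cohort)
        measured = []
        for rec_row in df.itertuples():
            spec = EEGSynthesisSpec(target_faa=rec_row.faa_e3 / 1000.0,
                                    duration_s=config.eeg_duration_s,
                                    seed=int(rng.integers(0, 2**31 - 1)))
            eeg = generate_eeg(spec)
            if config.write_eeg_files:
                fio.write_eeg_csv(eeg, out_dir / f"{rec_row.subject_id}.csv")
            measured.append(faa_from_recording(eeg, **config.eeg_params)["faa_reported"])
        df["faa_target_e3"] = df["faa_e3"]
        df["faa_e3"] = measured
        fio.write_cohort_csv(
            [c for c in cohort], out_dir / "cohort_target.csv")
        df.to_csv(out_dir / "cohort_measured.csv", index=False)
        report["faa_measurement_rmse"] = float(
            np.sqrt(np.mean((df["faa_e3"] - df["faa_target_e3"]) ** 2)))
        report["cohort"] = _analyze_cohort(df)

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
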