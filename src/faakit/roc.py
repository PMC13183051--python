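"""Empirical ROC analysis, AUC uncertainty, and Youden-optimal cutoffs.

The prognostic question is oriented so that *low* FAA predicts the positive
(poor-prognosis) class: a subject tests positive when score <= threshold.
AUC is the trapezoidal area, identical to the Mann–Whitney probability that
a random positive scores below a random negative (ties counted 1/2). AUC
standard errors use the Hanley–McNeil distribution-free approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import ContingencyTable, GroupSummary, TestResult, chi_square, pooled_t

POSITIVE_CLASS = "poor"


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # ascending candidate cutoffs
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    orientation: str  # lower_score_positive | higher_score_positive
    positive_class: str = POSITIVE_CLASS
    se: float | None = None
    ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float
    confusion: tuple  # ((tp, fn), (fp, tn))

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _validate_scores_labels(scores, labels, positive_class):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    pos = labels == positive_class
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present for ROC analysis")
    return scores, pos


def empirical_roc(scores, labels, orientation: str = "lower_score_positive",
                  positive_class: str = POSITIVE_CLASS,
                  with_se: bool = True) -> ROCCurve:
    """ROC over the distinct observed scores.

    With ``lower_score_positive`` a subject tests positive when
    score <= threshold; sensitivity is the positive-class rate so captured,
    1-specificity the negative-class rate. The curve starts at (0,0)
    (threshold below all scores) and ends at (1,1).
    """
    if orientation not in ("lower_score_positive", "higher_score_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")
    scores, pos = _validate_scores_labels(scores, labels, positive_class)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())

    thr = np.unique(scores)
    if orientation == "lower_score_positive":
        test_pos = scores[None, :] <= thr[:, None]
    else:
        test_pos = scores[None, :] >= thr[::-1, None]
    tpr = test_pos[:, pos].sum(axis=1) / n_pos
    fpr = test_pos[:, ~pos].sum(axis=1) / n_neg
    # anchor the degenerate all-negative operating point
    tpr = np.concatenate(([0.0], tpr))
    fpr = np.concatenate(([0.0], fpr))
    auc = float(np.trapezoid(tpr, fpr))

    curve = ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                     n_pos=n_pos, n_neg=n_neg, orientation=orientation,
                     positive_class=str(positive_class))
    if with_se and 0.0 < auc < 1.0:
        curve.se, curve.ci = hanley_mcneil_se(auc, n_pos, n_neg)
    elif with_se:
        curve.se, curve.ci = 0.0, (auc, auc)
    return curve


def mann_whitney_auc(scores, labels, orientation: str = "lower_score_positive",
                     positive_class: str = POSITIVE_CLASS) -> float:
    """Rank-statistic AUC: P(score_pos < score_neg) + 0.5 P(tie)."""
    scores, pos = _validate_scores_labels(scores, labels, positive_class)
    sp = scores[pos][:, None]
    sn = scores[~pos][None, :]
    less = (sp < sn).sum() if orientation == "lower_score_positive" else (sp > sn).sum()
    ties = (sp == sn).sum()
    return float((less + 0.5 * ties) / (pos.sum() * (~pos).sum()))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int,
                     z: float = 1.96) -> tuple[float, tuple[float, float]]:
    """Hanley–McNeil SE of an empirical AUC and its z-interval.

    Uses Q1 = A/(2-A), Q2 = 2A^2/(1+A); the CI auc ± z*se is clipped to
    [0, 1]. Degenerate AUC in {0, 1} gives se = 0.
    """
    if not 0 <= auc <= 1:
        raise ValueError("auc must lie in [0, 1]")
    if min(n_pos, n_neg) < 2:
        raise ValueError("need >= 2 subjects in each class")
    a = float(auc)
    if a in (0.0, 1.0):
        return 0.0, (a, a)
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    se = float(np.sqrt(var))
    lo = max(0.0, a - z * se)
    hi = min(1.0, a + z * se)
    return se, (lo, hi)


def confusion_at_threshold(scores, labels, threshold: float,
                           orientation: str = "lower_score_positive",
                           positive_class: str = POSITIVE_CLASS) -> CutoffResult:
    """Confusion table and sens/spec when testing positive at <= threshold
    (or >= under the reversed orientation)."""
    scores, pos = _validate_scores_labels(scores, labels, positive_class)
    if orientation == "lower_score_positive":
        test_pos = scores <= threshold
    else:
        test_pos = scores >= threshold
    tp = int((test_pos & pos).sum())
    fn = int((~test_pos & pos).sum())
    fp = int((test_pos & ~pos).sum())
    tn = int((~test_pos & ~pos).sum())
    return CutoffResult(cutoff=float(threshold),
                        sensitivity=tp / (tp + fn), specificity=tn / (tn + fp),
                        confusion=((tp, fn), (fp, tn)))


def metrics_from_confusion(tp: int, fn: int, fp: int, tn: int) -> dict:
    """Sensitivity, specificity and Youden J from explicit counts."""
    if min(tp + fn, fp + tn) == 0:
        raise ValueError("both classes must be represented")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {"sensitivity": sens, "specificity": spec,
            "sensitivity_pct": 100 * sens, "specificity_pct": 100 * spec,
            "youden_j": sens + spec - 1.0}


def youden_optimal(roc: ROCCurve, scores, labels) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1 over the curve's
    thresholds; ties broken by larger sensitivity, then lower cutoff."""
    best: CutoffResult | None = None
    for thr in roc.thresholds:
        cand = confusion_at_threshold(scores, labels, float(thr),
                                      orientation=roc.orientation,
                                      positive_class=roc.positive_class)
        if best is None:
            best = cand
            continue
        key = (round(cand.youden_j, 12), round(cand.sensitivity, 12), -cand.cutoff)
        best_key = (round(best.youden_j, 12), round(best.sensitivity, 12), -best.cutoff)
        if key > best_key:
            best = cand
    assert best is not None
    return best


def stratify_by_cutoff(df: pd.DataFrame, cutoff: float,
                       score_col: str = "faa_e3",
                       markers: tuple = ("gfap", "s100b", "gaba")) -> dict:
    """Split a cohort at the cutoff and rebuild the outcome and marker tables.

    Returns the prognosis 2x2 (rows good/poor, columns <=cutoff / >cutoff)
    with its chi-square test, and per-marker pre/post group summaries with
    pooled t tests comparing the strata.
    """
    scores = df[score_col].to_numpy(dtype=float)
    if cutoff < scores.min() or cutoff >= scores.max():
        raise ValueError("cutoff must split the cohort into two nonempty strata")
    le = df[scores <= cutoff]
    gt = df[scores > cutoff]

    counts = [[int((le.prognosis == g).sum()), int((gt.prognosis == g).sum())]
              for g in ("good", "poor")]
    table = ContingencyTable(counts=tuple(map(tuple, counts)),
                             row_labels=("good", "poor"),
                             col_labels=("le_cutoff", "gt_cutoff"))
    outcome_test = chi_square(table)

    marker_rows = {}
    for m in markers:
        for tp in ("pre", "post"):
            col = f"{m}_{tp}"
            if col not in df.columns:
                continue
            a = le[col].dropna().to_numpy()
            b = gt[col].dropna().to_numpy()
            r = pooled_t(a, b)
            marker_rows[col] = {
                "le_cutoff": GroupSummary.from_values(a),
                "gt_cutoff": GroupSummary.from_values(b),
                "t": abs(r.statistic), "df": r.df, "p": r.p,
            }
    return {"cutoff": float(cutoff), "n_le": len(le), "n_gt": len(gt),
            "outcome_counts": table, "outcome_test": outcome_test,
            "markers": marker_rows}


def roc_report(scores, labels, orientation: str = "lower_score_positive") -> dict:
    """One-stop summary: curve, Hanley–McNeil SE/CI and the Youden optimum."""
    curve = empirical_roc(scores, labels, orientation=orientation)
    best = youden_optimal(curve, scores, labels)
    return {
        "auc": curve.auc, "se": curve.se,
        "ci_lower": curve.ci[0], "ci_upper": curve.ci[1],
        "cutoff": best.cutoff, "youden": best.youden_j,
        "sensitivity_pct": 100 * best.sensitivity,
        "specificity_pct": 100 * best.specificity,
        "n_pos": curve.n_pos, "n_neg": curve.n_neg,
        "confusion": best.confusion,
    }
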