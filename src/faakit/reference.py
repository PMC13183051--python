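"""Published summary statistics of the reference pediatric status epilepticus cohort.

The source study (177 children, 126 good / 51 poor prognosis by GOS at one
month) released only group-level summaries, not subject-level data. Those
printed summaries are inputs here: they parameterize the synthetic-cohort
defaults and let the statistical battery be re-run end-to-end against the
published test statistics (worked-examples mode).

Continuous variables are (mean, sd) per group; categorical variables are
per-group counts. FAA is on the x1000 reporting scale. Serum markers are
summarized by FAA cutoff stratum (<=88.96 vs >88.96), pre and post
treatment: GFAP ng/L, S100-beta ug/L, GABA umol/L.
"""

from __future__ import annotations

N_GOOD = 126
N_POOR = 51

#: continuous covariates: name -> ((mean, sd) good, (mean, sd) poor, printed |t|)
CONTINUOUS_BY_PROGNOSIS = {
    "age_yr": ((6.54, 1.22), (6.28, 1.26), 1.272),
    "bmi": ((21.54, 1.94), (21.67, 1.88), 0.407),
    "picu_days": ((6.55, 1.28), (6.79, 1.08), 1.179),
    "faa_e3": ((89.10, 17.04), (66.64, 17.77), 7.844),
}

#: categorical covariates: name -> (row labels, good counts, poor counts, printed chi2)
CATEGORICAL_BY_PROGNOSIS = {
    "sex": (["male", "female"], [54, 72], [25, 26], 0.558),
    "se_duration_gt60": ([">60", "<=60"], [42, 84], [29, 22], 8.367),
    "epilepsy_history": (["yes", "no"], [37, 89], [17, 34], 0.270),
    "seizure_type": (["convulsive", "nonconvulsive"], [102, 24], [41, 10], 0.007),
    "time_to_cessation_gt30": ([">30", "<=30"], [25, 101], [19, 32], 5.894),
    "underlying_disease": (
        ["primary_epilepsy", "viral_bacterial", "other"], [42, 39, 45], [20, 18, 13], 1.729),
    "respiratory_failure": (["yes", "no"], [10, 116], [6, 45], 0.647),
    "vasopressor_use": (["yes", "no"], [7, 119], [6, 45], 2.057),
}

#: multivariable logistic model (outcome: poor prognosis = 1)
#: term -> (beta, se, wald, exp_beta)
LOGISTIC_TERMS = {
    "faa_e3": (-0.077, 0.013, 32.944, 0.926),
    "se_duration_gt60": (0.370, 0.416, 0.789, 1.447),
    "time_to_cessation_gt30": (1.010, 0.439, 5.308, 2.747),
    "const": (4.605, 0.999, 21.238, 99.961),
}

#: ROC of FAA for poor prognosis (lower FAA = positive)
ROC_FAA = {
    "auc": 0.805, "se": 0.035, "ci": (0.738, 0.873),
    "youden": 0.43, "sensitivity_pct": 90.20, "specificity_pct": 52.38,
    "cutoff": 88.96,
}

#: outcome counts by FAA cutoff stratum: {stratum: {prognosis: n}}
CUTOFF_OUTCOME_COUNTS = {
    "le_cutoff": {"good": 60, "poor": 46},
    "gt_cutoff": {"good": 66, "poor": 5},
}
N_LE_CUTOFF = 106
N_GT_CUTOFF = 71

#: serum markers by FAA cutoff stratum:
#: marker -> timepoint -> ((mean, sd) <=cutoff, (mean, sd) >cutoff, printed |t|)
MARKERS_BY_CUTOFF = {
    "gfap": {"pre": ((8.93, 1.20), (9.04, 1.19), 0.600),
             "post": ((6.04, 1.31), (5.17, 1.32), 4.317)},
    "s100b": {"pre": ((19.28, 4.11), (18.96, 4.26), 0.500),
              "post": ((10.54, 2.30), (8.32, 1.89), 6.747)},
    "gaba": {"pre": ((69.88, 10.41), (70.09, 10.55), 0.131),
             "post": ((61.87, 7.14), (54.35, 7.37), 6.780)},
}

#: sample-size planning constants used by the study
SAMPLE_SIZE_PLAN = {"pi": 0.139, "alpha": 0.05, "delta": 0.06, "dropout": 0.20}
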