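"""Cohort-level statistical battery.

Normality testing (Shapiro–Wilk), two-group comparison of continuous
variables by the pooled-variance Student t test (from raw vectors or from
published mean/sd/n summaries), contingency analysis by uncorrected Pearson
chi-square or Fisher's exact test, binary logistic regression with
Wald-based inference (odds ratios, 1.96-SE confidence intervals), GOS
dichotomization, and the one-proportion sample-size formula.

Conventions follow the common clinical-statistics (SPSS-style) output:
pooled t with df = n1+n2-2, chi-square without continuity correction, Wald
statistic (beta/se)^2 referred to chi-square(1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

Z_975 = 1.959963984540054  # normal 97.5% quantile; CI multiplier rounds to 1.96


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSummary:
    """mean ± sd with group size, as printed in clinical tables."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    @classmethod
    def from_values(cls, x: np.ndarray) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(n=x.size, mean=float(x.mean()), sd=float(x.std(ddof=1)))


@dataclass(frozen=True)
class ContingencyTable:
    counts: tuple  # r x c nested tuples of nonnegative ints
    row_labels: tuple = ()
    col_labels: tuple = ()

    def __post_init__(self) -> None:
        arr = self.as_array()
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if np.any(arr < 0) or arr.sum() == 0:
            raise ValueError("counts must be nonnegative with a positive total")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    method: str  # t_pooled | chi_square | fisher | shapiro_wilk

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")


@dataclass(frozen=True)
class LogisticTerm:
    name: str
    beta: float
    se: float

    @property
    def wald(self) -> float:
        return (self.beta / self.se) ** 2

    @property
    def p(self) -> float:
        return float(sst.chi2.sf(self.wald, df=1))

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def ci(self) -> tuple[float, float]:
        return (math.exp(self.beta - 1.96 * self.se),
                math.exp(self.beta + 1.96 * self.se))


@dataclass
class LogisticModelFit:
    terms: dict[str, LogisticTerm]
    llf: float
    n_iter: int
    converged: bool
    n_obs: int

    def table(self) -> pd.DataFrame:
        rows = []
        for t in self.terms.values():
            lo, hi = t.ci
            rows.append({"term": t.name, "beta": t.beta, "se": t.se,
                         "wald": t.wald, "p": t.p, "exp_beta": t.odds_ratio,
                         "ci_lower": lo, "ci_upper": hi})
        return pd.DataFrame(rows).set_index("term")


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

_GOS_ORDER = {"I": 1, "II": 2, "III": 3, "IV": 4, "V": 5}


def dichotomize_gos(gos_level: str | int) -> str:
    """Map a five-level GOS to the prognosis label: V -> good, I-IV -> poor."""
    if isinstance(gos_level, str):
        level = _GOS_ORDER.get(gos_level.strip().upper())
    else:
        level = int(gos_level) if gos_level in (1, 2, 3, 4, 5) else None
    if level is None:
        raise ValueError(f"GOS level must be I-V, got {gos_level!r}")
    return "good" if level == 5 else "poor"


def pooled_t_from_summaries(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Student pooled-variance t from printed mean/sd/n; df = n1+n2-2."""
    t, p = sst.ttest_ind_from_stats(g1.mean, g1.sd, g1.n,
                                    g2.mean, g2.sd, g2.n, equal_var=True)
    return TestResult(statistic=float(t), df=g1.n + g2.n - 2, p=float(p),
                      method="t_pooled")


def pooled_t(x1: np.ndarray, x2: np.ndarray) -> TestResult:
    """Pooled t on raw vectors; exactly the summary path on their mean/sd/n."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    if min(x1.size, x2.size) < 2:
        raise ValueError("each group needs >= 2 observations")
    return pooled_t_from_summaries(GroupSummary.from_values(x1),
                                   GroupSummary.from_values(x2))


def chi_square(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-square; errors on zero expected counts."""
    arr = table.as_array()
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi-square needs an r>=2 x c>=2 table")
    expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell count; use fisher_exact instead")
    stat, p, df, _ = sst.chi2_contingency(arr, correction=False)
    return TestResult(statistic=float(stat), df=float(df), p=float(p),
                      method="chi_square")


def fisher_exact(table: ContingencyTable) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 table (hypergeometric tail sum)."""
    arr = table.as_array()
    if arr.shape != (2, 2):
        raise ValueError("Fisher exact test requires a 2x2 table")
    _, p = sst.fisher_exact(arr.astype(int), alternative="two-sided")
    return TestResult(statistic=float("nan"), df=0.0, p=float(p), method="fisher")


def shapiro_wilk(x: np.ndarray) -> TestResult:
    """Shapiro–Wilk W and p (Royston algorithm); requires 3 <= n <= 5000."""
    x = np.asarray(x, float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro–Wilk needs 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk W is undefined for a constant vector")
    w, p = sst.shapiro(x)
    return TestResult(statistic=float(w), df=float(x.size), p=float(p),
                      method="shapiro_wilk")


def fit_logistic(design: pd.DataFrame | np.ndarray, outcome: np.ndarray,
                 add_constant: bool = True, maxiter: int = 100) -> LogisticModelFit:
    """Maximum-likelihood binary logistic regression with Wald inference.

    ``design`` holds the coded covariates (binary covariates as 0/1, FAA as
    its original value); ``outcome`` is 1 for the positive (poor-prognosis)
    class. A constant column is prepended unless ``add_constant=False``.
    Raises on (quasi-)separation or non-convergence rather than returning
    meaningless Wald statistics.
    """
    import statsmodels.api as sm

    X = pd.DataFrame(design).copy()
    X.columns = [str(c) for c in X.columns]
    y = np.asarray(outcome, float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be coded 0/1")
    if add_constant:
        X = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than model terms")

    with np.errstate(all="ignore"):
        try:
            res = sm.Logit(y, X).fit(disp=False, maxiter=maxiter,
                                     method="newton", tol=1e-10)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as e:
            raise ValueError(f"logistic fit failed: {e}") from e
    if not res.mle_retvals.get("converged", False):
        raise ValueError(
            f"logistic fit did not converge after {maxiter} iterations "
            f"(|beta|_max = {np.max(np.abs(res.params)):.3g})")
    if np.max(np.abs(res.params)) > 50:
        raise ValueError("diverging coefficients suggest complete separation")

    terms = {
        name: LogisticTerm(name=name, beta=float(res.params[name]),
                           se=float(res.bse[name]))
        for name in X.columns
    }
    return LogisticModelFit(terms=terms, llf=float(res.llf),
                            n_iter=int(res.mle_retvals.get("iterations", -1)),
                            converged=True, n_obs=int(res.nobs))


def sample_size(pi: float, alpha: float = 0.05, delta: float = 0.06,
                dropout: float = 0.0) -> dict:
    """One-proportion sample size N = z_{a/2}^2 * pi(1-pi) / delta^2.

    Returns the raw value, its ceiling, and the dropout-inflated ceiling
    (N_raw * (1+dropout), rounded up).
    """
    if not 0 < pi < 1:
        raise ValueError("pi must lie in (0, 1)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    if dropout < 0:
        raise ValueError("dropout must be nonnegative")
    z = sst.norm.ppf(1 - alpha / 2)
    raw = z ** 2 * pi * (1 - pi) / delta ** 2
    return {"n_raw": float(raw), "n": math.ceil(raw),
            "n_inflated": math.ceil(raw * (1 + dropout)), "z": float(z)}


# --------------------------------------------------------------------------
# Cohort-level battery (univariate table + logistic model from a DataFrame)
# --------------------------------------------------------------------------

def crosstab(df: pd.DataFrame, column: str, by: str = "prognosis",
             col_order: tuple = ("good", "poor")) -> ContingencyTable:
    sub = df[[column, by]].dropna()
    ct = pd.crosstab(sub[column], sub[by])
    ct = ct[[c for c in col_order if c in ct.columns]]
    return ContingencyTable(
        counts=tuple(tuple(int(v) for v in row) for row in ct.to_numpy()),
        row_labels=tuple(str(i) for i in ct.index),
        col_labels=tuple(str(c) for c in ct.columns))


def univariate_table(df: pd.DataFrame,
                     continuous: tuple = ("age_yr", "bmi", "picu_days", "faa_e3"),
                     categorical: tuple = ("sex", "se_duration_gt60",
                                           "epilepsy_history", "seizure_type",
                                           "time_to_cessation_gt30",
                                           "underlying_disease",
                                           "respiratory_failure",
                                           "vasopressor_use")) -> pd.DataFrame:
    """Good-vs-poor univariate screen: pooled t for continuous variables,
    Pearson chi-square (Fisher fallback on zero expected cells) for
    categorical ones. Listwise deletion per variable."""
    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        sub = df[[var, "prognosis"]].dropna()
        g = sub.loc[sub.prognosis == "good", var].to_numpy()
        p = sub.loc[sub.prognosis == "poor", var].to_numpy()
        r = pooled_t(g, p)
        rows.append({"variable": var, "kind": "continuous",
                     "good_mean": g.mean(), "good_sd": g.std(ddof=1),
                     "poor_mean": p.mean(), "poor_sd": p.std(ddof=1),
                     "statistic": abs(r.statistic), "df": r.df, "p": r.p,
                     "method": r.method})
    for var in categorical:
        if var not in df.columns:
            continue
        tab = crosstab(df, var)
        try:
            r = chi_square(tab)
        except ValueError:
            try:
                r = fisher_exact(tab)
            except ValueError:
                continue  # degenerate table (single level / r x c with empty cells)
        rows.append({"variable": var, "kind": "categorical",
                     "statistic": r.statistic, "df": r.df, "p": r.p,
                     "method": r.method})
    return pd.DataFrame(rows).set_index("variable")


def fit_prognosis_model(df: pd.DataFrame,
                        terms: tuple = ("faa_e3", "se_duration_gt60",
                                        "time_to_cessation_gt30")) -> LogisticModelFit:
    """Multivariable model: poor prognosis (=1) on the coded covariates."""
    sub = df[list(terms) + ["prognosis"]].dropna()
    y = (sub["prognosis"] == "poor").astype(float).to_numpy()
    return fit_logistic(sub[list(terms)], y)
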