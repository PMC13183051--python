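"""Synthetic EEG recordings and patient cohorts with controllable structure.

Stands in for the unavailable clinical data. Two generators:

* :func:`generate_eeg` — a two-frontal-channel resting recording whose
  alpha-band (default 10 Hz) amplitudes are solved analytically so the
  noise-free FAA equals ``target_faa`` exactly; pink background noise,
  raised-cosine blink transients and broadband artifact bursts are layered
  on at configurable rates.
* :func:`generate_cohort` — patient records whose stratum-conditional FAA
  moments, categorical marginals and serum-marker moments default to the
  reference cohort's published values; prognosis is either fixed by stratum
  (moment-matching mode) or drawn from a logistic model in FAA and
  time-to-seizure-cessation (model mode, for parameter-recovery studies).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import reference as ref
from .eeg import EEGRecording

GOS_LEVELS = ("I", "II", "III", "IV", "V")
#: default distribution over poor-prognosis GOS levels I..IV
POOR_GOS_WEIGHTS = (0.10, 0.20, 0.30, 0.40)


# --------------------------------------------------------------------------
# EEG synthesis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EEGSynthesisSpec:
    """Parameters of one synthetic resting EEG recording.

    target_faa : intended (P_F4-P_F3)/(P_F4+P_F3), |value| < 1
    duration_s / fs : length and sampling rate (500 Hz default)
    alpha_freq : alpha carrier frequency, within 8-13 Hz
    alpha_amp : RMS-scale carrier amplitude (uV)
    noise_sd : SD of the broadband pink+white background (uV)
    blink_rate / artifact_rate : events per minute
    n_extra_channels : additional scalp channels (Cz, Pz, ...) carrying
        background activity only, for re-referencing experiments
    """

    target_faa: float = 0.0
    duration_s: float = 240.0
    fs: float = 500.0
    alpha_freq: float = 10.0
    alpha_amp: float = 10.0
    noise_sd: float = 2.0
    blink_rate: float = 2.0
    artifact_rate: float = 0.5
    n_extra_channels: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.target_faa) < 1:
            raise ValueError(f"target_faa must satisfy |x| < 1, got {self.target_faa}")
        if self.fs <= 80.0:
            raise ValueError(f"fs must exceed 80 Hz (2 x 40 Hz analysis band), got {self.fs}")
        if not 8.0 <= self.alpha_freq <= 13.0:
            raise ValueError(f"alpha_freq must lie in [8, 13] Hz, got {self.alpha_freq}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.noise_sd < 0 or self.blink_rate < 0 or self.artifact_rate < 0:
            raise ValueError("noise_sd, blink_rate and artifact_rate must be nonnegative")


EXTRA_CHANNEL_POOL = ["Cz", "Pz", "C3", "C4", "P3", "P4", "O1", "O2"]


def _pink_noise(rng: np.random.Generator, n: int, fs: float, sd: float) -> np.ndarray:
    """Gaussian 1/f-shaped noise plus a white floor, scaled to SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = 1.0 / np.sqrt(f[nz])
    shape[0] = 0.0
    pink = np.fft.irfft(spec * shape, n=n)
    mix = pink / pink.std() + 0.5 * rng.standard_normal(n)
    return sd * mix / mix.std()


def _raised_cosine(width: int) -> np.ndarray:
    t = np.arange(width)
    return 0.5 * (1 - np.cos(2 * np.pi * t / (width - 1)))


def generate_eeg(spec: EEGSynthesisSpec) -> EEGRecording:
    """Synthesize a recording realizing ``spec`` (deterministic per seed).

    The F3/F4 alpha amplitudes a3, a4 are solved from the FAA definition:
    sinusoid power is a^2/2, so (a4^2-a3^2)/(a4^2+a3^2) = target_faa gives
    a3 = A*sqrt(1-t), a4 = A*sqrt(1+t). Slow sinusoidal amplitude jitter,
    common to both channels, leaves the power ratio untouched.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs

    a3 = spec.alpha_amp * math.sqrt(1.0 - spec.target_faa)
    a4 = spec.alpha_amp * math.sqrt(1.0 + spec.target_faa)
    jitter = 1.0 + 0.1 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    # bilaterally synchronous alpha: a common phase keeps spectral leakage
    # identical across channels, so the power ratio is exact
    phase = rng.uniform(0, 2 * np.pi)
    carrier = 2 * np.pi * spec.alpha_freq * t

    labels = ["F3", "F4"] + EXTRA_CHANNEL_POOL[: spec.n_extra_channels]
    x = np.zeros((len(labels), n))
    x[0] = a3 * jitter * np.sin(carrier + phase)
    x[1] = a4 * jitter * np.sin(carrier + phase)
    for ch in range(len(labels)):
        x[ch] += _pink_noise(rng, n, spec.fs, spec.noise_sd)

    # blinks: 0.5 s raised-cosine deflections on the frontal channels, with
    # a broadband onset transient (sharp lid movement) that leaks into the
    # alpha band asymmetrically — this is what artifact rejection must catch
    n_blinks = rng.poisson(spec.blink_rate * spec.duration_s / 60.0)
    width = int(round(0.5 * spec.fs))
    for _ in range(n_blinks):
        start = rng.integers(0, max(1, n - width))
        amp = rng.uniform(150.0, 300.0)
        env = _raised_cosine(width)
        pulse = amp * env * (1.0 + 0.2 * rng.standard_normal(width))
        x[0, start:start + width] += pulse
        x[1, start:start + width] += 0.9 * pulse

    # artifact bursts: ~1 s of high-amplitude broadband noise on all channels
    n_bursts = rng.poisson(spec.artifact_rate * spec.duration_s / 60.0)
    bwidth = int(round(1.0 * spec.fs))
    for _ in range(n_bursts):
        start = rng.integers(0, max(1, n - bwidth))
        x[:, start:start + bwidth] += rng.normal(0.0, 200.0, size=(len(labels), bwidth))

    return EEGRecording(samples=x, fs=spec.fs, channel_labels=labels)


# --------------------------------------------------------------------------
# Cohort synthesis
# --------------------------------------------------------------------------

def _default_covariate_marginals() -> dict:
    """Stratum-conditional category probabilities from the reference counts."""
    out: dict[str, dict[str, dict[str, float]]] = {}
    for name, (cats, good, poor, _) in ref.CATEGORICAL_BY_PROGNOSIS.items():
        out[name] = {
            "categories": list(cats),
            "good": [c / sum(good) for c in good],
            "poor": [c / sum(poor) for c in poor],
        }
    return out


def _default_marker_moments() -> dict:
    return {
        m: {tp: {"le_cutoff": tuple(v[0]), "gt_cutoff": tuple(v[1])}
            for tp, v in tps.items()}
        for m, tps in ref.MARKERS_BY_CUTOFF.items()
    }


def _default_continuous_moments() -> dict:
    return {
        name: {"good": tuple(v[0]), "poor": tuple(v[1])}
        for name, v in ref.CONTINUOUS_BY_PROGNOSIS.items()
        if name != "faa_e3"
    }


#: marginal intercept calibrated so the model-mode poor rate matches 51/177
DEFAULT_OUTCOME_MODEL = {"intercept": 4.8165, "beta_faa": -0.077, "beta_time": 1.010}


@dataclass
class CohortConfig:
    """Generator configuration; defaults reproduce the reference cohort."""

    n_good: int = ref.N_GOOD
    n_poor: int = ref.N_POOR
    faa_mean_good: float = 89.10
    faa_sd_good: float = 17.04
    faa_mean_poor: float = 66.64
    faa_sd_poor: float = 17.77
    faa_cutoff: float = 88.96  # marker moments condition on this stratum
    covariate_marginals: dict = field(default_factory=_default_covariate_marginals)
    continuous_moments: dict = field(default_factory=_default_continuous_moments)
    marker_moments: dict = field(default_factory=_default_marker_moments)
    outcome_model: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_MODEL))
    mode: str = "moment_matching"  # or "model"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_good < 0 or self.n_poor < 0:
            raise ValueError("group sizes must be nonnegative")
        if self.n_good + self.n_poor == 0:
            raise ValueError("cohort must contain at least one subject")
        if min(self.faa_sd_good, self.faa_sd_poor) <= 0:
            raise ValueError("FAA standard deviations must be positive")
        if self.mode not in ("moment_matching", "model"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for name, spec in self.covariate_marginals.items():
            for grp in ("good", "poor"):
                p = spec[grp]
                if abs(sum(p) - 1.0) > 1e-12:
                    raise ValueError(f"probabilities for {name}/{grp} must sum to 1")
                if any(q < 0 for q in p):
                    raise ValueError(f"negative probability in {name}/{grp}")


@dataclass
class PatientRecord:
    """One subject: covariates, FAA (x1000 scale), serum markers, outcome."""

    subject_id: str
    age_yr: float
    sex: str
    bmi: float
    se_duration_gt60: int
    epilepsy_history: int
    seizure_type: str
    time_to_cessation_gt30: int
    picu_days: float
    faa_e3: float
    underlying_disease: str
    respiratory_failure: int
    vasopressor_use: int
    gfap_pre: float
    gfap_post: float
    s100b_pre: float
    s100b_post: float
    gaba_pre: float
    gaba_post: float
    gos_level: str

    @property
    def prognosis(self) -> str:
        from .stats import dichotomize_gos
        return dichotomize_gos(self.gos_level)


_BINARY_YES = {"yes": 1, "no": 0, ">60": 1, "<=60": 0, ">30": 1, "<=30": 0}


def calibrate_intercept(config: CohortConfig, target_rate: float | None = None,
                        n_mc: int = 500_000, seed: int = 12345) -> float:
    """Solve the model-mode intercept giving a chosen marginal poor rate.

    Monte-Carlo over the FAA stratum mixture and the time>30min marginal;
    bisection on the intercept. Used once to fix the packaged default.
    """
    from scipy.optimize import brentq

    if target_rate is None:
        target_rate = config.n_poor / (config.n_good + config.n_poor)
    rng = np.random.default_rng(seed)
    w_good = config.n_good / (config.n_good + config.n_poor)
    good = rng.random(n_mc) < w_good
    faa = np.where(good,
                   rng.normal(config.faa_mean_good, config.faa_sd_good, n_mc),
                   rng.normal(config.faa_mean_poor, config.faa_sd_poor, n_mc))
    tm = config.covariate_marginals["time_to_cessation_gt30"]
    p_gt30 = (w_good * tm["good"][tm["categories"].index(">30")]
              + (1 - w_good) * tm["poor"][tm["categories"].index(">30")])
    t30 = (rng.random(n_mc) < p_gt30).astype(float)
    bf = config.outcome_model["beta_faa"]
    bt = config.outcome_model["beta_time"]

    def excess(b0: float) -> float:
        lp = b0 + bf * faa + bt * t30
        return float((1.0 / (1.0 + np.exp(-lp))).mean()) - target_rate

    return float(brentq(excess, -30.0, 30.0))


def _draw_categorical(rng, spec: dict, stratum: str, size: int) -> np.ndarray:
    idx = rng.choice(len(spec["categories"]), size=size, p=spec[stratum])
    return np.array(spec["categories"])[idx]


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw ``n_good + n_poor`` records (deterministic per seed + config).

    moment_matching mode: prognosis fixed by stratum; every stratum mean/sd
    converges to its configured value. model mode: FAA and covariates come
    from the marginal mixture and prognosis is Bernoulli under the logistic
    outcome model, so refitting the regression is a well-posed recovery
    problem.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_good + config.n_poor

    if config.mode == "moment_matching":
        strata = np.array(["good"] * config.n_good + ["poor"] * config.n_poor)
        faa = np.where(
            strata == "good",
            rng.normal(config.faa_mean_good, config.faa_sd_good, n),
            rng.normal(config.faa_mean_poor, config.faa_sd_poor, n))
    else:
        w_good = config.n_good / n
        prior_good = rng.random(n) < w_good
        faa = np.where(prior_good,
                       rng.normal(config.faa_mean_good, config.faa_sd_good, n),
                       rng.normal(config.faa_mean_poor, config.faa_sd_poor, n))

    # covariates, stratum-conditional in moment-matching mode, pooled otherwise
    cov: dict[str, np.ndarray] = {}
    for name, spec in config.covariate_marginals.items():
        if config.mode == "moment_matching":
            vals = np.empty(n, dtype=object)
            for s in ("good", "poor"):
                sel = strata == s
                vals[sel] = _draw_categorical(rng, spec, s, int(sel.sum()))
        else:
            w_good = config.n_good / n
            pooled = {"categories": spec["categories"],
                      "mix": [w_good * pg + (1 - w_good) * pp
                              for pg, pp in zip(spec["good"], spec["poor"])]}
            idx = rng.choice(len(pooled["categories"]), size=n, p=pooled["mix"])
            vals = np.array(pooled["categories"])[idx]
        cov[name] = vals

    if config.mode == "model":
        t30 = np.array([_BINARY_YES[v] for v in cov["time_to_cessation_gt30"]], float)
        m = config.outcome_model
        lp = m["intercept"] + m["beta_faa"] * faa + m["beta_time"] * t30
        poor = rng.random(n) < 1.0 / (1.0 + np.exp(-lp))
        strata = np.where(poor, "poor", "good")

    cont: dict[str, np.ndarray] = {}
    for name, mom in config.continuous_moments.items():
        vals = np.empty(n)
        for s in ("good", "poor"):
            sel = strata == s
            mu, sd = mom[s]
            vals[sel] = rng.normal(mu, sd, int(sel.sum()))
        cont[name] = vals

    # serum markers condition on the FAA cutoff stratum, not on prognosis
    faa_stratum = np.where(faa <= config.faa_cutoff, "le_cutoff", "gt_cutoff")
    markers: dict[str, np.ndarray] = {}
    for m, tps in config.marker_moments.items():
        for tp, strata_mom in tps.items():
            vals = np.empty(n)
            for s in ("le_cutoff", "gt_cutoff"):
                sel = faa_stratum == s
                mu, sd = strata_mom[s]
                vals[sel] = rng.normal(mu, sd, int(sel.sum()))
            markers[f"{m}_{tp}"] = vals

    gos = np.where(
        strata == "good", "V",
        rng.choice(GOS_LEVELS[:4], size=n, p=POOR_GOS_WEIGHTS))

    records = []
    for i in range(n):
        records.append(PatientRecord(
            subject_id=f"S{i + 1:04d}",
            age_yr=round(float(cont["age_yr"][i]), 2),
            sex=str(cov["sex"][i]),
            bmi=round(float(cont["bmi"][i]), 2),
            se_duration_gt60=_BINARY_YES[str(cov["se_duration_gt60"][i])],
            epilepsy_history=_BINARY_YES[str(cov["epilepsy_history"][i])],
            seizure_type=str(cov["seizure_type"][i]),
            time_to_cessation_gt30=_BINARY_YES[str(cov["time_to_cessation_gt30"][i])],
            picu_days=round(float(cont["picu_days"][i]), 2),
            faa_e3=float(faa[i]),
            underlying_disease=str(cov["underlying_disease"][i]),
            respiratory_failure=_BINARY_YES[str(cov["respiratory_failure"][i])],
            vasopressor_use=_BINARY_YES[str(cov["vasopressor_use"][i])],
            gfap_pre=float(markers["gfap_pre"][i]),
            gfap_post=float(markers["gfap_post"][i]),
            s100b_pre=float(markers["s100b_pre"][i]),
            s100b_post=float(markers["s100b_post"][i]),
            gaba_pre=float(markers["gaba_pre"][i]),
            gaba_post=float(markers["gaba_post"][i]),
            gos_level=str(gos[i]),
        ))
    return records


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in records])
    df["prognosis"] = [r.prognosis for r in records]
    return df
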