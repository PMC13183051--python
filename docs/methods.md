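# Methods

## The prognostic model

Frontal alpha asymmetry is the normalized difference in alpha-band
(8–13 Hz) power between the right (F4) and left (F3) frontal electrodes,

FAA = (P_F4 − P_F3) / (P_F4 + P_F3),

dimensionless, in [−1, 1], reported ×10³ by clinical convention. The
package treats the "×10⁻³ μV" unit label sometimes attached to reported
FAA values as a reporting scale only: a ratio of two powers has no unit,
so `FAAIndex.reported` is defined as exactly 1000 × ratio.

Prognosis is the GOS at one month dichotomized as V = good, I–IV = poor.
The analysis chain is: univariate screen (pooled t / χ²) → binary
logistic regression of poor prognosis on the significant covariates (FAA
on its original scale, binary covariates coded 0/1) → ROC of FAA with the
poor class positive → Youden-optimal cutoff → cutoff-stratified outcome
and serum-marker tables.

## Signal chain

* **Re-referencing.** Common average over scalp channels only; ocular and
  mastoid channels (VEOG/HEOG/A1/A2/...) are excluded from the average.
  The transform is idempotent. With exactly two scalp channels the
  average reference is degenerate — it cancels the component common to
  F3 and F4 and halves the asymmetric one — so `faa_from_recording`
  applies it only when more than two scalp channels are present. On
  synthetic two-channel recordings the chain is therefore
  bandpass → mask → Welch → FAA, which keeps the round-trip exact.
* **Bandpass.** 4th-order Butterworth, 0.3–40 Hz, applied
  forward–backward (`sosfiltfilt`) for zero phase distortion of alpha
  power. A 10 Hz tone passes within 1 %; 60 Hz mains and DC are
  attenuated below 5 %.
* **Artifact rejection.** A reproducible surrogate for manual editing:
  samples exceeding z = 6 robust standard deviations (1.4826 × MAD about
  the channel median) on any scalp channel are masked, padded by 0.2 s.
  The robust scale keeps a clean oscillation (max |z| ≈ 0.95) untouched
  while blinks (150–300 μV) and bursts (~200 μV SD) sit far above
  threshold. Masked samples are excluded by dropping every Welch window
  that overlaps them.
* **Spectral estimation.** Welch PSD, Hann window, 2 s windows, 50 %
  overlap, density scaling, no detrending (the signal is already
  high-passed at 0.3 Hz). 2 s windows give 0.5 Hz resolution: eleven
  grid points in [8, 13] inclusive. Band power is the arithmetic mean of
  in-band PSD values; because the FAA ratio is invariant to the constant
  bandwidth factor, mean and integral readings give identical FAA.
* **Condition handling.** Recordings are treated as one continuous
  resting condition; when eyes-open/eyes-closed segments exist they are
  concatenated after artifact rejection. No condition-specific analysis
  is attempted because none is defined for the reference results.

## Synthetic EEG

The generator is built to make the pipeline's accuracy analytically
checkable rather than to imitate ictal morphology:

* the alpha carrier is a fixed-frequency sinusoid (default 10 Hz) with
  common slow amplitude jitter and a common phase on F3/F4; amplitudes
  a3 = A√(1−t), a4 = A√(1+t) realize target FAA = t exactly (sinusoid
  power a²/2), and the shared phase keeps spectral leakage identical
  across channels, so the noise-free round-trip is exact to ~1e−9;
* background noise is 1/f-shaped Gaussian noise with a white floor
  (default SD 2 μV against a 10 μV carrier);
* blinks are 0.5 s raised-cosine deflections of 150–300 μV on the
  frontal channels (F4 at 0.9 × F3), carrying a 20 % broadband onset
  transient. The transient is what leaks into the alpha band
  asymmetrically; without it, blink energy is almost entirely below 4 Hz
  and artifact rejection would have nothing measurable to recover;
* artifact bursts are ~1 s of 200 μV broadband noise on all channels.

What this does **not** emulate: 1/f alpha-band structure, spindles,
asymmetric physiological alpha phase lags, electrode drift, or any
seizure activity. Passing round-trip tests therefore demonstrates the
pipeline's correctness on controlled spectra, not clinical performance.

## Synthetic cohorts

* **Moment-matching mode** (default): prognosis fixed by stratum
  (126 good / 51 poor by default); FAA drawn from stratum-conditional
  normals (89.10 ± 17.04 / 66.64 ± 17.77, ×10⁻³ scale); categorical
  covariates drawn from the stratum-conditional frequencies of the
  reference univariate table; serum markers drawn conditional on each
  subject's FAA against the 88.96 cutoff, because the reference marker
  table is stratified by cutoff, not by prognosis. Within-stratum
  normality of FAA is an assumption — consistent with the reference
  analysis using t tests after Shapiro–Wilk — not an established fact.
* **Model mode** (for parameter recovery): FAA and covariates come from
  the marginal mixture and prognosis is Bernoulli with
  logit p(poor) = β₀ + β_FAA·FAA + β_time·1{time>30 min},
  defaults β_FAA = −0.077, β_time = 1.010. The intercept default 4.8165
  was calibrated by Monte-Carlo (`calibrate_intercept`) so the marginal
  poor rate equals 51/177 under the default mixture.
* Poor-prognosis GOS levels are weighted 0.10/0.20/0.30/0.40 for I–IV;
  only the V-vs-rest dichotomy matters downstream.
* Identical seed + config ⇒ bit-identical cohorts and recordings
  (`numpy.random.default_rng` throughout).

## Statistical conventions

* **t test:** Student pooled-variance, df = n₁+n₂−2. This is the variant
  under which every printed reference t value (7.844, 4.317, 6.747,
  6.780, 1.272, 0.407, 1.179, …) reproduces from the printed summaries;
  Welch's t does not reproduce them.
* **χ²:** Pearson without continuity correction, again the variant that
  reproduces the printed values (8.367, 5.894, 1.729 with df 2, 2.057, …).
  Zero expected cells raise an error recommending Fisher's exact test,
  whose two-sided p sums hypergeometric probabilities ≤ that of the
  observed table.
* **Logistic regression:** Newton MLE (statsmodels `Logit` behind the
  module surface), convergence tolerance 1e−10; Wald statistic (β/SE)²
  against χ²₁; CI multiplier fixed at 1.96 to match the convention of
  SPSS-style clinical tables. Separation and non-convergence raise
  errors instead of returning unstable estimates.
* **ROC:** thresholds are the distinct observed scores; a subject tests
  positive when score ≤ threshold (lower-score-positive). Only this
  orientation reproduces the reference operating point
  (sensitivity 90.20 % = 46/51, specificity 52.38 % = 66/126). AUC is
  trapezoidal and provably equals the Mann–Whitney statistic with ties
  half-weighted; reversing the orientation maps AUC → 1 − AUC. Youden
  ties are broken by higher sensitivity, then lower cutoff.
* **AUC uncertainty:** Hanley–McNeil with Q1 = A/(2−A), Q2 = 2A²/(1+A),
  CI = AUC ± 1.96·SE clipped to [0, 1]. The reference SE of 0.035 at
  AUC 0.805 (n 51/126) is *not* reproducible by this formula (≈ 0.040);
  it evidently derives from subject-level information, so the SE is
  validated structurally against the closed form, and the published CI
  is checked by reconstruction (0.805 ± 1.96×0.035 brackets the printed
  0.738–0.873), not by equality.
* **Sample size:** N = z²_{α/2}·π(1−π)/δ². At π = 0.139, δ = 0.06 this
  gives 127.7, although the reference planning text rounds to "about
  126"; the implementation reports the formula value.
* **Missing data:** listwise per test; degenerate tables in the
  univariate screen (a single observed level at small n) are skipped
  rather than forced through an inapplicable test.

## Problem sizes in the test and acceptance runs

Moment-matching convergence is checked at n = 10⁴ per stratum (2 %
tolerance); blink-rejection benefit over 50 paired 30 s recordings; the
simulated-AUC study uses 500 cohorts of 126/51 (mean within 0.03 of the
binormal value Φ(Δμ/√(σ₁²+σ₂²)) ≈ 0.819, with 0.805 inside the central
95 % interval); logistic parameter recovery uses 100 cohorts of n = 5000.
For the recovery criterion each coefficient is required to fall inside
its own Wald 95 % CI in ≥ 90 of 100 seeds: per-coefficient coverage is
nominally 95 %, so this margin is robust, whereas the *joint* coverage
of two 95 % intervals is ≈ 90 % by construction and would make a joint
criterion a coin flip; the joint rate is reported (not asserted) by the
acceptance script.

## Known limitations

* The artifact surrogate is amplitude-only; low-amplitude artifacts
  (muscle tone, electrode pops below threshold) pass through.
* EDF support is 16-bit uncompressed EDF; EDF+ annotations are ignored.
* No ICA/EOG regression, no multiple-testing correction (none is used in
  the reference analysis), no DeLong SE, no cross-validated cutoff.
* The binary time-to-cessation predictor yields a two-point ROC; its
  AUC equals (sensitivity + specificity)/2 and is not separately
  analyzed.
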