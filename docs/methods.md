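# Methods

This note documents the models, conventions and numerical choices behind
`irsurv`, in the order the pipeline runs them, followed by what the
synthetic data does and does not emulate, and known limitations.

## Data model and formats

A **hyperspectral cube** is an `(rows, cols, wavenumbers)` array of
absorbances with a strictly increasing wavenumber axis in cm⁻¹ (the
default grid is 990–3800 cm⁻¹ in 6 cm⁻¹ steps, 469 points). On disk a
cube is a JSON sidecar header plus a flat little-endian float64 payload in
row-major order; masks are 0/1 CSV or single-channel PNG; cohort tables
are TSV with columns `patient_id  time_months  event [risk_label]
[true_class] [score]`. Serialisation is canonical (`%.17g` floats,
round-trip parsing), so write→read→write is byte-identical — this is what
makes end-to-end determinism testable. Pixel coordinates are 0-based
`(row, col)`, row 0 at top, everywhere.

## Preprocessing

**Co-registration.** The tumour mask, drawn on an adjacent stained
section, is aligned to the infrared image by an exhaustive search over
integer wrap-around translations within `±max_shift` (default 4 px),
maximising Pearson correlation between the shifted mask and the amide-I
(1650 cm⁻¹) image binarised at its Otsu threshold. Band lookup uses the
nearest grid point. Ties break to the smallest offset magnitude, then row
before column. Wrap-around (rather than zero-fill) translation makes a
planted shift exactly recoverable and keeps the overlap count constant
across candidates; sub-pixel registration is out of scope. This works
only if tumour differs from surrounding tissue in amide-I intensity — in
the generator, tumour regions are more protein-dense than stroma
(`background_density` = 0.6), mirroring the cellularity contrast that
makes real amide-I co-registration possible.

**Interferent correction.** Each raw spectrum *s* is regressed by
ordinary least squares on the tissue reference, the paraffin and
atmospheric references, and a constant + linear baseline (axis rescaled
to [0, 1]):

    s ≈ a·tissue + b·paraffin + c·atmospheric + d₀ + d₁·u(axis)

The corrected spectrum is `(s − b·paraffin − c·atmospheric − d₀ −
d₁·u)/a`; dividing by the multiplicative coefficient *a* normalises
section thickness (an EMSC-style model). `thickness_correction: none`
skips the division for users who prefer rejection-only handling. Spectra
with `a ≤ 10⁻³` are flagged unusable and fall through to the quality
filter rather than raising. Correction is idempotent by construction
(re-correcting yields a = 1, other coefficients ≈ 0). Per-coefficient
standard errors from `σ̂²(XᵀX)⁻¹` support recovery checks against planted
truth. Resonant-Mie scattering correction is deliberately out of scope.

**Quality filter.** A spectrum is retained iff its amide-I absorbance
lies in `[quality_min, quality_max]` (defaults 0.1–2.0, the usual
detector-linearity window) **and** amide-I height / noise ≥ `snr_min`
(default 3), with noise estimated as the standard deviation of first
differences in the signal-poor 1750–1800 cm⁻¹ band divided by √2 (the
first-difference estimator is insensitive to residual baseline).

**Fingerprint extraction.** Retained tumour-mask pixels are collected
into a flat datapoint × wavenumber matrix restricted to the closed
interval [1000, 1800] cm⁻¹ (on the 6 cm⁻¹ grid: 1002–1800, 134 points),
each row tagged with `(patient_id, row, col)`.

## Outcome-driven stratification

Candidate cut-offs are midpoints between consecutive distinct follow-up
times. At a candidate *t*: patients who died at or before *t* are
high-risk, patients followed beyond *t* low-risk, and patients censored
at or before *t* are excluded (configurable to `treat-as-low`; the
exclusion choice reflects that an early-censored patient is uninformative
about death by *t*). Candidates leaving either group below
`min_group_size` (default 3) are skipped; the admissible candidate with
the largest log-rank statistic wins, ties to the smaller cut-off.

The log-rank statistic uses the standard O−E / hypergeometric-variance
form with events processed before censorings at tied times, and the
p-value comes from χ²(1). Two properties of this construction deserve
emphasis, both demonstrated by the test suite rather than "fixed":

* **Anti-conservatism.** The maximum over candidates is not χ²(1)
  distributed; `null_calibration` shows the maximised statistic exceeds
  the χ²(1) 95 % quantile in essentially all one-class null simulations
  at n = 29. The unadjusted p-value is reported as-is, as headline
  analyses of this kind typically do, with the calibration utility as the
  corrective lens.
* **Early-cut-off bias.** Because a small extreme early-death group has a
  small variance term, `(O−E)²/V` tends to peak at the smallest
  admissible cut-offs. Under overlapping exponential class-time
  distributions the selected cut-off therefore sits *inside* the
  high-hazard class rather than at the class boundary, and the induced
  endpoint misassigns ~30 % of patients relative to the latent class even
  at extreme hazard ratios. The cut-off is an endpoint-defining device —
  it always yields strongly separated groups — not a consistent estimator
  of a latent class boundary.

`label_endpoint` turns a fixed cut-off into supervised labels: high = died
at or before the cut-off, low = followed beyond it, censored before it =
excluded from modelling.

## Classification and patient scores

PCA keeps the top 7 right singular vectors of the mean-centred datapoint
matrix (component signs fixed so the largest-magnitude loading is
positive); logistic regression on the component scores is fitted by IRLS
on the ridge-penalised likelihood (penalty −½λ‖w‖², intercept
unpenalised, λ = 10⁻⁴ by default). The small ridge exists purely to keep
separable in-bag problems finite; convergence requires every penalised-
gradient component below 10⁻⁸ within 200 iterations.

Bootstrap OOB evaluation resamples **patients** (not datapoints) with
replacement — all datapoints of an out-of-bag patient are excluded from
fitting, so within-patient correlation cannot leak into the estimates —
and refits PCA *inside* every replicate on the in-bag datapoints only.
Replicates whose OOB set is empty or single-class are discarded and
redrawn. Per replicate: OOB datapoints are scored, each OOB patient gets
the median of their datapoint probabilities (midpoint rule at even
counts), and AUROC (pair-concordance with ties counted half), sensitivity
and specificity (score ≥ 0.5 called high-risk; the operating point is
configurable) are computed over OOB patients. Summaries are medians and
half-interquartile ranges over replicates (B = 500 by default); the
dispersion measure is labelled half-IQR wherever reported. A final model
fitted on all labelled data produces the patient prediction scores used
downstream, for every patient with retained datapoints.

## Survival analysis

Kaplan–Meier uses the product-limit estimator over distinct event times;
censorings at an event time remain at risk through that time's events.
The 95 % bands use the exponential Greenwood transform
`Ŝ^exp(±z√v̂)` with `v̂ = ĉ/(ln Ŝ)²`, `ĉ = Σ d/(n(n−d))`, which keeps
bands inside [0, 1]; the band is `[Ŝ, Ŝ]` where Ŝ = 1 and omitted where
Ŝ = 0 (transform undefined). The Cox model maximises the Breslow partial
likelihood by Newton–Raphson (steps damped to ±5, convergence |U(β)| <
10⁻⁸); ties are Breslow-handled (Efron out of scope); intervals are Wald,
`exp(β ± 1.96·SE)`, matching the conventional reporting shape. Monotone
likelihood (perfect separation) is detected by |β| ≥ 50 or vanishing
information and returned flagged with β capped, never raised. The reverse
analysis enumerates midpoints between distinct patient scores, assigns
high risk at score ≥ threshold, and returns the log-rank maximiser
(smaller threshold on ties) with KM curves for both groups; the same
extreme-group preference as in stratification applies, so the chosen
threshold is the exhaustive maximiser, not necessarily the class
boundary.

## Synthetic cohorts: what is emulated, and what is not

Defaults were chosen once, for realism at the study's scale:

| parameter | default | rationale |
|---|---|---|
| n_patients | 29 | the study cohort size |
| axis | 990–3800 cm⁻¹, 6 cm⁻¹ | the instrument's acquisition grid |
| core_size | 40 px | ~1 mm core at ~10 µm pixels, downscaled; per-patient pixel counts were not published |
| tumour_fraction | 0.4 | cores "largely of tumour" with surrounding stroma |
| hazard_high / hazard_low | 0.12 / 0.008 month⁻¹ | median survival ≈ 5.8 vs 87 months: an aggressive-recurrence group (deaths within the first year) against a low-risk group with ≈ 70 % five-year survival |
| censor_max | 120 months | a ten-year accrual/follow-up window, uniform entry |
| effect_size | 1.0 | +10 % amplitude of the 1240 cm⁻¹ peak per unit, localised so a spectral classifier *can* find it |
| noise_sd | 0.01 abs | typical pixel noise relative to amide-I ≈ 1 |
| paraffin coeff | U(0.1, 0.5) | visible but sub-dominant contamination |
| thickness | U(0.7, 1.3) | ±30 % section-thickness variation |
| background_density | 0.6 | stroma less protein-dense than tumour; provides the amide-I registration contrast |

All randomness flows from one `numpy.random.default_rng(seed)` stream in
a fixed draw order, so identical configurations are byte-identical. The
pipeline fans a root seed out per stage as `(seed·1000003 + stage) mod
2³¹` so stages can be rerun in isolation.

Not emulated: optical physics (Mie/dispersion artefacts), spatial
correlation of noise or biology between neighbouring pixels, intra-tumour
heterogeneity of the class effect, non-exponential survival,
informative censoring, and cohort-level covariates. Passing tests
therefore demonstrate that the *pipeline machinery* is correct and
well-calibrated under its stated model — not that the biological signal
in real FTIR data is of any particular size.

## Problem sizes used by tests and the acceptance script

The test suite runs reduced geometries chosen to keep the full suite
under a minute apart from the bootstrap checks: 10–16 px cores for
pipeline tests, 16 px cores with 29 patients and B = 200 for the
classifier calibration checks, 1 px "cohort-only" cores where only
survival machinery is exercised. `scripts/acceptance.py` uses 29
patients, 20×20 cores, effect size 2.0 and B = 200 (≈ 1 minute). The
analysis scripts use the same scale with seed 7.

## Known limitations

* The maximally selected cut-off (and score threshold) prefer small
  extreme groups, as described above; users wanting boundary-style splits
  should raise `min_group_size` or fix the cut-off externally.
* The unadjusted stratification p-value is optimistic by construction;
  use `null_calibration` for an honest null reference.
* The Cox hazard ratio is per unit of a [0, 1] score; with near-separated
  scores the point estimate is large and unstable while the Wald interval
  is honest about it. The separation flag should be checked before
  quoting the estimate.
* Quality-filter thresholds (0.1–2.0 absorbance, SNR ≥ 3) are defaults
  for the synthetic data's noise model and should be revisited per
  instrument.
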