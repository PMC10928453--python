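# irsurv — infrared microspectroscopy prognosis pipeline

`irsurv` re-implements, as a tested and reusable pipeline, a prognosis
workflow for oral squamous cell carcinoma (OSCC) built on FTIR
microspectroscopy of tumour tissue cores. Given hyperspectral tissue-core
images (an absorbance spectrum per ~10 µm pixel), tumour annotation masks
drawn on an adjacent stained section, and patient follow-up data, it:

1. **preprocesses** the spectra — co-registers each mask against the
   amide-I (1650 cm⁻¹) image, removes paraffin/atmospheric/baseline
   interference with an EMSC-style linear model and normalises section
   thickness, filters poor-quality spectra, and extracts the fingerprint
   region (1000–1800 cm⁻¹);
2. **stratifies** patients into high-/low-risk groups from outcome data
   alone, choosing the survival cut-off *t\** that maximises the two-group
   log-rank statistic over all candidate cut-offs;
3. **classifies** datapoint spectra against that endpoint with PCA (7
   components) + logistic regression, estimating AUROC / sensitivity /
   specificity by patient-level bootstrap out-of-bag (OOB) resampling, and
   scores each patient by the **median** of their datapoint probabilities;
4. runs **survival analysis** on the patient scores — Kaplan–Meier curves
   with exponential Greenwood 95 % bands, a univariate Cox
   proportional-hazards fit, and a *reverse analysis* that re-assigns risk
   groups at the score threshold maximising the log-rank statistic.

The core statistics are implemented from their definitions: the log-rank
statistic `(Σ(d₁ᵢ − dᵢn₁ᵢ/nᵢ))² / Σ Vᵢ` with hypergeometric variance
`Vᵢ = dᵢ(n₁ᵢ/nᵢ)(1 − n₁ᵢ/nᵢ)(nᵢ − dᵢ)/(nᵢ − 1)`; the product-limit
estimator `Ŝ(t) = Π(1 − dᵢ/nᵢ)` with bands `Ŝ^exp(±z√v̂)` on the
log(−log) scale; Breslow partial-likelihood Newton–Raphson for Cox; and a
ridge-stabilised IRLS logistic regression. `lifelines` and `scikit-learn`
appear only as independent cross-checks in the test suite.

Because the kind of clinical FTIR dataset this targets is rarely
deposited, the package ships a first-class synthetic-data module
(`irsurv.synthdata`) that generates cohorts with known ground truth:
Gaussian-peak tissue spectra (amide I/II), per-pixel thickness, paraffin
and atmospheric contamination, baseline drift, pixel noise, a tunable
class-dependent spectral effect, and exponential survival with
class-dependent hazards plus uniform censoring. Every pipeline stage is
validated against the planted truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
29-patient cohort (20×20-pixel cores, planted effect size 2.0, seed 7) and
write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_preprocess.py
python analysis/03_stratify.py
python analysis/04_classify.py
python analysis/05_survival.py
```

which prints, stage by stage:

```
wrote 29 patients to results/data
  latent classes: 16 high / 13 low; 18 deaths observed
co-registration offsets recovered: [(-1, -2)] (planted shift (1, 2) → expected (-1, -2))
retained 4642/4642 tumour-pixel spectra across 29 patients
fingerprint axis: 1002-1800 cm⁻¹ (134 points)
survival cut-off: 1.35 months (log-rank statistic 41.44, unadjusted p = 1.21e-10)
  caution: under a one-class null the maximised statistic exceeds the
  chi-squared(1) 95% quantile in 100% of simulations
bootstrap OOB over 200 replicates:
  median AUROC       0.812 (±0.087 half-IQR)
Cox on patient scores: HR 4.07e+05 (95% CI 127-1.3e+09; p = 0.0017)
reverse analysis: score threshold 0.115 → 16 high / 13 low; log-rank p = 1.02e-05
```

Reading the output: the planted mask misregistration is recovered exactly
and every tumour spectrum survives quality filtering. The outcome-driven
cut-off lands at 1.35 months — maximally selected statistics favour small
extreme early-death groups, so the endpoint is noisier than the latent
class (hence AUROC 0.81 rather than ~1.0, which is what the classifier
achieves against the planted class itself). The reverse analysis
nevertheless recovers a 16/13 split matching the latent classes exactly,
with strongly separated survival curves. The Cox hazard ratio is *per unit
score*; with scores concentrated near 0 and 1 it is large with a wide
Wald interval — the interval width, not the point estimate, carries the
message at n = 29.

A `irsurv` command-line tool exposes the same stages
(`irsurv run --config run.yaml`, plus `simulate`, `preprocess`,
`stratify`, `classify`, `survival` subcommands); `docs/methods.md`
documents the model, conventions and limitations.

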