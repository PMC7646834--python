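# Methods

`histomol` implements a dual-modality workflow for subtyping renal tumors in
FFPE tissue sections: pixel-wise classification of MALDI mass spectrometry
imaging (MSI) data, sample-wise classification of rapid LC-MS/MS
microproteomics profiles, and a decision table integrating the two
per-patient calls.  Because no patient-level raw data is publicly available
for this workflow, the package ships a synthetic-data module that generates
both modalities with known ground truth; every pipeline stage is validated
against that truth or against independent analytic oracles.

## MSI track

### Phantom model (synthetic_data)

A phantom section is a `grid x grid` pixel raster with a central tumor blob
(one of ccRCC / RO / ChRCC), a surrounding stroma ring, and background.  The
spectrum of a tissue pixel is

    I(m) = TIC * [ sum_p A_p exp(-(m - m_p)^2 / (2 sigma^2)) ] + B exp(-lambda (m - m_min)) + eps(m)

with Gaussian peaks of FWHM 1.0 Da at the class signature masses
(ccRCC: m/z 723.5, 704.5; RO: 806.5, 1640.0; ChRCC: 1169.5, 1039.5 — the
discriminating masses reported for these subtypes), three shared tissue
peaks, and two stroma-only peaks.  Per-pixel peak amplitudes vary with CV
0.3, the per-pixel TIC factor is log-normal with CV 0.2, the baseline decays
exponentially (amplitude 20 a.u., 0.002 /Da), and eps is Gaussian noise
(SD 2 a.u.); intensities are clipped at zero.  The m/z axis spans
600–3500 Da at 0.5 Da steps (the acquisition range; the analysis grid is
finer, see below).  Random streams are split per pixel (seed sequence
`[seed, x, y]`), so subsetting a region leaves other pixels' draws
unchanged.

Cohorts add patient-level heterogeneity: each patient's signature
amplitudes are scaled by a log-normal factor with CV 0.25.  Two special
constructions exist:

* **Sarcomatoid analog** — one ChRCC-labelled patient whose tumor carries a
  0.5/0.5 convex mixture of the ChRCC and ccRCC *mean* signatures.  The two
  mixture components share one common patient factor; independent per-class
  factors would re-tilt the designed mixture and change what the phantom is
  supposed to emulate (a genuinely mixed phenotype).
* **RO/ChRCC overlap** — RO and ChRCC signatures blended into each other by
  a configurable fraction (1.0 = identical signatures), emulating the
  spectral similarity of these two subtypes; blended components likewise
  share one patient factor.

What the phantom does **not** emulate: isotope envelopes, mass-calibration
drift, matrix clusters, detector saturation, spatial intensity gradients,
and within-tumor biological gradients.  Passing benchmarks therefore show
that the pipeline recovers the designed statistical structure, not that it
would reach the same accuracy on real tissue.

### Preprocessing (msi_preprocess)

* **Baseline**: rolling minimum over ±25 Da followed by a moving-average
  smooth of the same width, clipped from above by the signal.  The vendor
  baseline algorithm is proprietary; this standard estimator preserves
  isolated peak heights within 5% while removing offsets exactly.
* **TIC normalization**: every spectrum is scaled to the dataset-mean total
  ion current (not to 1.0), keeping intensities in instrument-like units.
  Idempotent; all-zero spectra are an error naming the pixel.
* **Peak picking**: local maxima with SNR >= 3 from every 10th spectrum
  (both configurable); noise is 1.4826 x MAD per spectrum.  A noise-free
  spectrum passes every positive maximum.
* **Alignment**: greedy in ascending m/z against the group's running
  intensity-weighted mean, repeated to a fixed point, so no two aligned
  peaks are closer than the tolerance.
* **Resampling**: "height" mode takes the maximum intensity within
  ±0.125 Da (half the analysis step) of each reference peak; dense binning
  linearly interpolates onto the inclusive grid 700.00, 700.25, …,
  2500.00 Da — 7201 features.

### Segmentation (msi_segmentation)

Spatial shrunken centroid clustering: from a seeded k-means++ partition,
each iteration computes cluster means, the pooled within-cluster SD `s_j`
and its median `s0`, forms `d_kj = (xbar_kj - xbar_j) / (m_k (s_j + s0))`
with `m_k = sqrt(1/n_k - 1/n)`, soft-thresholds `d_kj` by the shrinkage
parameter `s`, rebuilds centroids from the surviving contrasts, and
reassigns each pixel to the cluster minimizing the spatially smoothed
standardized squared distance.  Smoothing averages scores over a Chebyshev
radius-r neighborhood with Gaussian weights
`alpha_u = exp(-||u||^2 / (2 (r/2)^2))`, optionally multiplied by adaptive
similarity weights `beta_u = exp(-||x_u - x_c||^2 / (2 sigma_hat^2))`
(`sigma_hat^2` = mean squared neighbor distance), renormalized to sum 1.
Empty clusters are dropped; iteration stops at label convergence.  With
r = 0, s = 0 the procedure reduces to standardized k-means from the same
initialization.  Defaults for the phantom benchmark: r = 1, k_init = 4
(tumor / stroma / background plus one spare), s = 3.

Tumor pixels are selected by comparing clusters with a reference annotation
(in the benchmark, the phantom's ground-truth tumor mask stands in for the
pathologist's HE annotation).  Overlap criteria: Jaccard (spec default) or
containment (fraction of the cluster inside the mask) — the workflow uses
containment at 0.5 because it remains correct when the tumor splits into
several clusters.

### Classification (msi_classify)

PLS-DA: PLS2 regression (NIPALS) of mean-centered spectra on mean-centered
one-hot class indicators; no variance scaling.  Scores are the raw
continuous predictions — one per class per pixel.  Validation is strictly
leave-one-patient-out: all pixels of the held-out patient are scored by a
model trained on the remaining patients, and every training fold must keep
at least two patients per class.  The benchmark uses 5 components; a
component-count scan (`choose_n_components`, capped at 34) maximizes mean
LOPO pixel accuracy with ties going to the smaller count — on phantoms with
two informative masses per class the accuracy plateaus by 3–4 components.

**Patient call**: median pixel score per class; the highest median wins;
any class whose median lies within 10% of the winning median is reported as
indistinguishable (`RO/ChRCC`-style calls).  A non-positive winning median
is "unclassifiable".  The rule is scale-invariant.

## Proteomics track

### Table model (synthetic_data)

400 proteins with base log2 abundance ~ N(25, 1.5^2); 10 proteins per class
are shifted +2.0 log2 units (4-fold — marker-grade effects at or above the
2-fold threshold the volcano analysis itself treats as meaningful) in their
class.  The cohort is 12 ccRCC / 11 RO / 5 ChRCC patients with 2–6
extraction spots each; per-(patient, protein) noise SD 0.4 and per-spot
noise SD 0.5 log2 units.  Missingness is logistic in the true log2 value
(`logit p = 18 - 0.8 x`), so low-abundance proteins are missing more often
(MNAR); contaminant and reverse decoy rows are appended and flagged.  The
optional outlier patient replaces the last patient of its assigned class
with a convex mixture of two class mean profiles (default 0.5/0.5
ChRCC/ccRCC — the sarcomatoid analog).

### Statistics (proteomics_pipeline)

Processing order is fixed: flag filter → log2 → ≥70% valid-value filter →
one-way ANOVA with Benjamini-Hochberg control at FDR 0.01 on the
**unimputed** valid values → down-shifted normal imputation (mean
`mu - 1.8 sigma`, SD `0.3 sigma`, per sample column — the standard
left-censored MNAR model and its conventional constants) only for the
multivariate views.  Running ANOVA before imputation avoids significance
inflated by imputed values; the opposite order is available by applying
`impute_normal` first.  Heatmaps use row Z-scores; hierarchical clustering
defaults to correlation distance with average linkage.  The two-group
volcano contrast uses Welch's t-test with significance at p <= 0.01 and
>= 2-fold difference.

PCA prediction ellipses use the F-based region
`(x - xbar)' S^-1 (x - xbar) <= 2 (n-1)(n+1) / (n (n-2)) F_0.95(2, n-2)`,
which keeps 95% coverage for a *new* observation even at small n (a
chi-square radius undercovers there).

### SVM classification (proteomics_classify)

One-vs-rest SVM (cost 10, RBF gamma = 1/(n_features · feature variance)) on
per-fold standardized features under seeded stratified k-fold CV (default
k = 5).  Per-class decision values are the sample scores; argmax predicts.
Folds are stratified at the extraction-spot level by default, matching the
published design; patient-grouped folds (`groups=`) are the stricter option
when spots within a patient are correlated.  Feature-count optimization
re-ranks proteins by one-way ANOVA F inside each training fold and
evaluates the CV error for decreasing counts; the curve locates the
smallest panel with zero error.

## Integration

Decision table over the two per-patient calls:

1. either side irregular → **further validation**
2. MSI ambiguous between set S, LC-MS/MS class ∈ S → the LC-MS/MS class
3. both unambiguous and equal → that class
4. unambiguous but different → LC-MS/MS class **/further validation**

Conflicts defer to proteomics, the track with the lower cross-validated
error.  Irregularity rules:

* **(a) MSI co-scoring**: the runner-up median reaches ≥ 60% of the winning
  median and the pair is not {RO, ChRCC} (expected spectral neighbors).
  The threshold is deliberately *not* the 10% ambiguity margin: raw PLS
  medians of a designed 50/50 two-class mixture land at 65–95% of the
  winner (class-score calibration and patient heterogeneity), while clean
  patients stay below ~45%, so 60% separates "both classes high" from
  normal runner-up levels.  Ambiguity (rule 2) keeps the 10% margin.
* **(b) proteomics PCA outlier**: at least half of the patient's extraction
  spots fall outside the 95% prediction ellipse of its predicted class,
  where the ellipse is computed with that patient's spots held out (a
  prediction region describes a new observation; letting the suspect
  patient shape its own reference masks exactly the outliers the screen
  exists to find).

## Benchmark scales and determinism

The end-to-end MSI benchmark uses 23 patients (9/9/5) on 14x14 grids
(~55 tumor pixels each, ~1200 tumor pixels total, 7201 features) and runs
in well under a minute on one CPU; the proteomics benchmark (10 replicate
28-patient designs) takes seconds.  A single master seed derives per-stage
seeds (`stage_seed`), every run writes a manifest (config hash, seed,
library versions, outputs), and reruns with the same config are
byte-identical.

## Known limitations

* The phantom's peak and noise model is far simpler than MALDI-TOF reality
  (see above); benchmark accuracies are upper bounds tied to the designed
  effect sizes, not forecasts for clinical data.
* PLS-DA class scores are uncalibrated; the 10% margin and 60% co-scoring
  thresholds are conventions on raw scores, not probabilities.
* Sample-level CV folds can place spots of one patient in training and test
  simultaneously; patient-grouped folds are provided and recommended for
  patient-level claims.
* The segmentation objective (spatially smoothed discriminant score) is a
  heuristic; monotone descent is guaranteed only in the plain k-means limit
  (r = 0, s = 0).
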