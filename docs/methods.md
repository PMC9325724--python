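# Methods

## The problem

Neonatal respiratory morbidity (NRM — respiratory distress syndrome or
transient tachypnea of the newborn) is the leading complication of late
preterm delivery, and no non-invasive test reliably grades fetal lung
maturity. The approach implemented here quantifies fetal-lung texture on
routine B-mode ultrasound: a region of interest (ROI) over the lung is
delineated (free-hand, or a fixed 40×40-pixel square), a large catalog of
radiomics descriptors is computed from the ROI, a small informative subset
is selected, and an imbalance-aware boosted classifier converts the
selected features plus two clinical covariates — gestational age (GA, in
weeks) and a binary pregnancy-complication flag (gestational diabetes or
pre-eclampsia, "GDM or PE") — into a risk probability in [0, 1]. A
probability strictly above 0.5 assigns the high-risk group.

The patient images behind this design are not publicly available, so the
package ships a synthetic cohort generator with the same statistical
structure; everything downstream of image + mask is identical for real and
synthetic data.

## Feature catalog (430 features)

* **Morphological (15)** — shape descriptors of the ROI mask (area,
  perimeter, equivalent diameter, eccentricity, solidity, extent, axis
  lengths, circularity, convex area, bounding-box aspect, compactness,
  elongation, a 2-D sphericity analogue, perimeter-to-area ratio),
  computed from the largest connected component via
  `skimage.measure.regionprops`.
* **Texture (73)** — on the min–max-quantized ROI (default 16 grey
  levels): 14 first-order statistics of the raw in-mask intensities, 26
  grey-level co-occurrence (GLCM) features at pixel distance 1, a
  12-feature GLCM subset at distance 2, 16 grey-level run-length (GLRLM)
  features and 5 neighbourhood grey-tone difference (NGTDM) features.
* **Wavelet (342)** — a single-level orthonormal Haar decomposition of the
  mask bounding-box crop yields approximation / horizontal / vertical /
  diagonal sub-bands; per sub-band the same 14 first-order, 26 + 24 GLCM
  (distances 1 and 2), 16 GLRLM and 5 NGTDM features (85 × 4 = 340), plus
  two sub-band energy summaries (detail energy fraction, sub-band energy
  entropy).

The family totals (15 / 73 / 342) are a documented catalog configuration;
the correctness surface is each formula, which is tested against
brute-force enumeration oracles on random patches. Texture matrices are
built on in-mask pixels only: co-occurrence pairs with an endpoint outside
the mask are dropped, runs truncate at the mask boundary, and NGTDM
neighbourhood means use in-mask 8-neighbours. GLCMs are symmetrised,
normalized and averaged over the four 2-D directions; direction-averaged
contrast and covariance appear under the "Mean of …" names. Formula
conventions follow the canonical radiomics (IBSI-style) definitions;
degenerate cases (single occupied grey level, zero marginal entropy, zero
standard deviation) are guarded to 0 so extracted vectors are always
finite.

Quantization is uniform min–max binning into `Ng` right-open bins (top
value into the top bin; constant patches map to level 1). `Ng = 16` by
default, configurable. Because binning is per-patch min–max, features on
normalized matrices are invariant to adding a constant to the image.

Wavelet details: Haar, level 1, zero-padded borders (`pywt.dwt2`,
`mode="zero"`); for even crop sizes the transform is orthonormal, so
sub-band energies sum to the crop energy (tested at 1e-6 relative).
Out-of-mask pixels inside the bounding box are filled with the in-mask
mean before the transform; the mask is downsampled to sub-band resolution
(a coefficient counts as in-mask when any pixel of its 2×2 support is).

## Feature selection

Univariate screening (two-sample pooled t-test per continuous feature,
chi-squared without continuity correction for the binary clinical
covariate) is reported for description only — selection does not filter on
p, and the selected set may include features with p > 0.05.

Selection proper ranks features by out-of-bag (OOB) permutation importance
of a bagged regression forest on the 0/1 labels: 500 trees by default,
unlimited depth, `mtry = floor(sqrt(p))`, each tree fit on a bootstrap
sample; per tree the OOB squared error is computed before and after
permuting one feature's OOB values, and importance is the mean error
increase across trees, divided by its across-tree standard deviation
(the classical normalized permutation importance; the raw mean is also
reported). The top 20 radiomics features are kept (ties broken by catalog
order) and GA and "GDM or PE" are always appended, giving 22 model inputs.

## Classifiers

**RUSBoost** (random under-sampling + AdaBoost) handles the ≈1:3 class
imbalance. Each round draws a resample containing every minority case and
an equal-sized majority under-sample (drawn without replacement with
probability proportional to the current boosting weights; uniform drawing
is available), fits a depth-limited `DecisionTreeClassifier`, computes the
weighted error ε on the **full** weighted training set, sets
α = ½ ln((1−ε)/ε) and reweights examples AdaBoost-style. Rounds with
ε ≥ 0.5 are re-drawn (up to 10 times), ε is floored at 1e-10, and the
per-round resample class counts are logged so the balance property is
checkable. Binary discrete AdaBoost is used (equivalent in effect to
AdaBoost.M2 for two classes). The ensemble score of a class is the sum of
α over trees voting for it; the risk probability is the softmax of the two
class scores (the logistic of the vote margin), and exactly 0.5 maps to
the low-risk group because the high-risk rule is a strict inequality.

**Clinical baseline** — an RBF support-vector machine on (GA, complication)
with a per-class misclassification cost; the positive-class cost defaults
to the inverse class frequency so the classifier attends to the rare
positives. Inputs are standardized internally; the decision function
supplies the continuous score for ROC analysis.

Tree depth (grid {1, 2, 3} by default in the pipeline) is chosen by
bootstrap tenfold cross-validation: stratified tenfold splits on bootstrap
resamples of the training set, scored out of fold by AUC, best mean AUC
wins (ties by grid order). 50 boosting rounds are used in the pipeline;
performance plateaued well below that on cohorts of this size.

## Evaluation

* Sensitivity, specificity, accuracy, PPV and NPV from the confusion
  matrix at the 0.5 cut-off (strictly-greater rule); metrics with an empty
  denominator are reported as undefined rather than NaN.
* 95% CIs by case-resampled percentile bootstrap (2000 replicates by
  default; resamples on which a statistic is undefined are skipped).
* AUC by the rank-sum (Mann–Whitney) estimator with midrank tie
  correction; ROC points at every distinct threshold.
* Calibration (equal-width probability bins: mean predicted vs observed
  rate), cumulative gain and lift curves as data tables.
* ICC(2,1) — two-way random effects, absolute agreement, single measure —
  quantifies per-feature stability across the three delineations
  (free-hand A, free-hand B, square), with the McGraw–Wong F-based 95% CI.
  Zero between-case variance is reported as 0 with a degeneracy flag.
* A utility reconstructs the unique integer confusion matrix consistent
  with printed percentage metrics and split sizes by exhaustive search
  over (TP, TN); it errors unless exactly one matrix matches.

## Synthetic cohort generator

Per case the generator draws GA uniformly on 28–37 weeks, a complication
flag with probability 0.332, and a latent lung-maturity score
`latent ~ Normal(0.35·(GA−33), 1)` — texture matures with gestation. The
NRM label follows a logistic model whose deficit-scale form is

    logit P(NRM) = b0 − 0.2·(GA−33) + 0.5·complication − 1.8·(latent − 0.35·(GA−33))

with `b0` calibrated by Monte-Carlo so the expected prevalence is 0.234
(the study cohort's rate). Risk is thus driven by the maturity *deficit*
relative to GA, plus direct prematurity and complication effects. This
makes GA alone and texture alone moderately predictive while their
combination recovers the deficit — the qualitative pattern reported for
the clinical, radiomics and combined models. The implied population AUCs
are ≈0.62 (clinical), ≈0.80 (latent texture) and ≈0.86 (full model); the
coefficients are free parameters of the generator, fixed as defaults and
documented here because no quantitative effect sizes are published.

Images are speckled random fields: with `z = tanh(texture_effect·latent/2)`,
a Gaussian field smoothed at correlation length `2 + z` pixels and
amplitude-scaled by `1 + 0.25·z` is modulated by multiplicative Rayleigh
speckle of relative strength `0.3·(1 − 0.5·z)` (immature lungs render more
granular), mapped to 8-bit. Each case carries two jittered 12-vertex
star-convex polygon masks ("radiologists" A and B) and a centered 40×40
square. Everything is reproducible from the config seed.

What the generator does **not** emulate: anatomy (ribs, heart, shadowing),
depth-dependent attenuation and focusing, operator variation beyond mask
jitter, and any real relation between echotexture and histological lung
maturity. Passing tests therefore demonstrate that the pipeline recovers
the statistical structure it assumes, not clinical validity on real
images.

## Problem sizes and numerical choices

The pipeline default mirrors the study design (210 training / 85 testing
cases, three delineations, 18 metric panels and one ICC table). The
model-comparison study (`fetalrad.pipeline.ordering_study`) uses 210
training and 200 held-out cases per seed at 128×128 pixels, importance
forests of 300 trees and a depth grid of {1, 2} — sizes chosen so a full
multi-seed replication runs on a laptop in minutes while keeping the AUC
ranking stable against held-out sampling noise. Tolerances: brute-force
oracle agreement at 1e-9; Haar energy conservation at 1e-6 relative;
bootstrap and forest procedures are exactly reproducible given seeds.

## Known limitations

* The published 342-feature wavelet composition cannot be uniquely
  recovered from the feature counts alone; the catalog documented above is
  one consistent composition and is configurable.
* Real-data absolute performance (e.g. test AUC 0.83) is not reproducible
  without the original images; the synthetic surface targets the ordering
  and calibration properties instead.
* The quantization level, resampling and mother wavelet of the original
  feature-extraction toolchain are not published; defaults (16 levels,
  Haar) are documented and configurable.
* ICC values on synthetic cohorts reflect the generator's mask jitter, not
  inter-radiologist variability.
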