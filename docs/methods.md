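# Methods

## Measurement model

The package measures area-based percent breast density on processed
("for presentation") 2D mammograms. The underlying assumption is that the
pectoralis major muscle and fibroglandular tissue have correlated
radiographic intensity on the same image, so the muscle — easy for any
radiologist to delineate in the MLO view — can serve as an internal
reference that absorbs acquisition-to-acquisition variation in exposure,
compression and detector response. Formally:

* reference `m` = median of all pixel values in the operator's rectangular
  muscle ROI (even counts: mean of the two central order statistics; ROI
  zeros are included, since the ROI is defined as "all pixels in the
  rectangle" — an ROI whose median is zero is rejected as misplaced);
* threshold `T = c·m` with the multiplicative calibration constant
  `c = 0.72` by default;
* dense mask = breast pixels with value `≥ T` on the CC view;
* `PD% = 100·N_dense/N_breast`.

Because the pipeline is a pure ratio of counts above a threshold that
itself scales with the image, `PD%` is invariant under any positive
rescaling of intensities of both views — the property that makes the
method robust to exposure differences. It is also deterministic:
identical inputs give bit-identical results.

The constant is configurable. The wording from which the method derives is
ambiguous about direction (a muscle-to-gland *ratio* of 0.72 would more
naturally imply division); the multiplicative form is implemented as
stated, and a user who prefers the other reading can pass
`constant = 1/0.72`. `estimate_constant` implements the calibration
procedure itself (mean per-image muscle/gland median ratio with a t-based
CI), so the constant can be re-derived on any local calibration sample.

## Background segmentation

The background definition is literal: a pixel is background iff it is zero
*and* its entire 8-neighbourhood is zero, with off-image neighbours treated
as zero. The complement is the breast. Two consequences are intentional:

* the one-pixel rim of zeros touching tissue counts as breast — the
  definition's own boundary behaviour, preserved exactly;
* isolated zero holes inside tissue remain breast.

An alternative `component` mode (largest border-touching zero-valued
connected component = background) is available for robustness on images
whose background is not perfectly flat, but `literal` is the default and
is what the acceptance checks exercise. The normalization layer guarantees
the rule's precondition: inverted-photometric sources are mapped to
white-is-dense and re-anchored so the background is exactly zero. Whether
any VOI/windowing transform should be applied before thresholding is left
to the caller; the package operates on stored values after photometric
normalization only.

## Reporting and classification

Percent density is reported both as a real number and as an integer in
1–100: half rounds away from zero, and any nonzero dense area reports at
least 1 (0 is reserved for a strictly empty dense set). BI-RADS
4th-edition bands are right-closed 25-point intervals — A (0,25],
B (25,50], C (50,75], D (75,100], 0 → A — chosen so that the dense
dichotomy `PD% > 50` coincides exactly with C ∪ D; this makes collapsing
a 4×4 agreement table to 2×2 an exact marginal sum.

## Agreement statistics

Differences are oriented software minus reference, so a positive bias
means the automated method reads higher.

* **Bland-Altman**: bias = mean difference, with a Student-t 95% CI;
  limits of agreement = bias ± 1.96·SD (sample SD, n−1); Shapiro-Wilk on
  the differences; one-sample t against zero; Pearson correlation of
  differences vs pair means as the proportional-bias check. Identical
  inputs return bias 0 and LoA (0, 0) with the undefined test statistics
  as NaN; constant pair means raise, because the proportional-bias
  correlation is then meaningless. The nonparametric LoA variant is out
  of scope.
* **ICC**: two-way random effects, absolute agreement, single measure
  (ICC(2,1)), computed from the ANOVA mean squares of the n×2 matrix; CI
  by the McGraw-Wong F interval with Satterthwaite degrees of freedom.
  This is the standard form for two-method agreement when both "raters"
  are considered random. Perfect agreement returns a collapsed CI.
* **Cohen's kappa**: unweighted, with the large-sample null-hypothesis
  variance for the z statistic (the variant that reproduces the published
  z values for the packaged reference table, 20.97 and 16.26). Weighted
  kappa is out of scope.
* **Constant estimator**: mean of per-image muscle/gland ratios with a
  t interval; a single pair yields a point estimate and a signalled
  (None) CI.

Shapiro-Wilk, t, Pearson and the F/t quantiles come from scipy; the
agreement arithmetic itself is implemented here and cross-checked in the
test suite against independent oracles (explicit-sum recomputations, and
pingouin's ICC(A,1) as an external reference).

## Synthetic phantoms

The phantom generator emulates exactly the image features the pipeline
relies on, and nothing more: an exact-zero background; a half-elliptical
breast of uniform adipose intensity attached to the chest-wall edge;
elliptical glandular blobs placed by rejection sampling (areas budgeted so
their union approaches the target dense fraction, with small top-up blobs
closing the residual; realized fraction recorded exactly); on the MLO
view, a triangular muscle wedge of intensity `ratio × glandular`; optional
Gaussian noise added inside tissue only and clipped at zero, so the
background rule stays valid. Everything is reproducible from the spec's
seed.

Ground truth is bookkept under the pipeline's own background definition:
the breast-area truth is the geometric breast plus its one-pixel zero rim
(the 3×3 dilation of the nonzero region), since those rim pixels are
breast by the literal rule. With zero noise the pipeline therefore
recovers the realized dense fraction *exactly*, which the tests assert
bit-for-bit.

Default conditions: 256×256 pixels, adipose 300, glandular 1000 (16-bit
scale), ratio 0.72 (so muscle 720 and, at the default constant, threshold
518.4 — comfortably between adipose and glandular), target dense fraction
0.4, six blobs, zero noise. The noise-robustness checks use
`noise_sd = 0.1 × (glandular − threshold)` ≈ 48, under which the measured
density stays within 2 percentage points of truth across seeds; with
these margins, misclassified pixels require >4.5σ noise excursions.

What passing phantom tests do **not** show: performance on real
parenchymal texture, scattered radiation, compression artifacts, skin
folds, implants, or muscle inhomogeneity — the phantom is a correctness
instrument for the algorithm, not a realism benchmark. Clinical-scale
agreement numbers (ICC against radiologists, bias, limits of agreement)
require real mammograms and are not asserted by this package.

## Numerical and design choices

* Coordinates are 0-based, row-major, half-open everywhere.
* The dense comparison is `≥` (a pixel exactly at threshold is dense).
* Percent-density reporting rounds half away from zero and clamps to ≥1
  when any dense pixel exists.
* Per-subject aggregation over the two breasts, where needed, is the mean
  of the per-image percents (`aggregate_subject`).
* The 291-subject visual-vs-software BI-RADS table ships as a packaged CSV
  (`data/birads_agreement_291.csv`) so the categorical-agreement
  statistics have an exactly reproducible regression target.
* Acceptance checks run at reduced phantom sizes (192–256 px) and 1000
  coverage simulations at n = 231 per calibration sample — sizes chosen so
  the whole validation completes in seconds while keeping the binomial
  error of the coverage estimate below one percentage point.

## Known limitations

* No automatic pectoral-muscle detection: the ROI is supplied as
  coordinates (scriptable replacement for an interactive cursor).
* Only single-frame grayscale DICOM and 8/16-bit grayscale PNG/TIFF are
  accepted; raw "for processing" and multi-frame DICOM are out of scope.
* No volumetric density, no vendor calibration, no thickness/exposure
  correction, and no graded density within dense tissue.
* The Shapiro-Wilk result is exposed as (statistic, p); no z
  transformation of the statistic is provided.
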