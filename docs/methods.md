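# Methods

## The quantification operator

A B-mode frame is a 2-D grid of 8-bit intensities ("Gray units", GU) with
known axial and lateral pixel spacing in mm. The analysis region of interest
(ROI) extends axially from the pleural line to the bottom of the image and,
by default, over the full width. Conventions fixed here:

- **ROI top row.** The first image row at or below the supplied pleural
  depth; the pleural-line row itself is included. A pleural depth of 0 makes
  the ROI the whole image, so the score degenerates to the plain image mean.
- **Slice profile.** ROI rows are grouped into consecutive depth bins of 0.2
  mm (configurable); a trailing partial slice is kept. The per-slice value is
  the arithmetic mean of its pixels. The pixel-count-weighted mean of slice
  means is algebraically identical to the ROI pixel mean; the tests verify
  this to 1e-9 together with the histogram route below.
- **Score.** The 256-bin frequency distribution of ROI intensities and its
  mean. No pixel is dropped: the histogram is defined on the whole ROI.
- **Classifier.** Positive iff mean GU > 48, *strictly*. The strict form is
  the only convention consistent with the source data, where a hemithorax
  scoring exactly 48 was read as negative and one scoring 52 as positive,
  and with the reported 41/44 sensitivity.
- **Pleural depth is an input.** The original operator placed the ROI
  manually. A heuristic detector (brightest axially-smoothed row within a
  search band, default 0.5 mm to half depth) is provided as an aid and
  recovers the simulator's ground truth to within 1 mm, but callers can and
  should override it when the depth is known. A flat image raises a
  detection-failure error rather than returning a guess.
- **Ingest.** Images are converted to 8-bit grayscale on read. DICOM:
  single-frame monochrome only (color Doppler rejected), MONOCHROME1
  inverted, values outside 0–255 min–max rescaled, pixel spacing from
  `PixelSpacing` or an explicit override. PNG: spacing must be supplied.
  Scanner settings (gain, focus, dynamic range of the machine) are treated
  as acquisition metadata, never used in computation: the score is defined
  on the displayed 0–255 image.

## The embedded cohort and its reconstruction

The study cohort is embedded as 49 per-hemithorax rows (44 CT-positive, 5
CT-negative) with labels from four methods (CT reference, chest X-ray,
visual and quantitative lung ultrasound), CT lesion geometry and Gray units.
The remaining 15 CT-negative hemithoraxes were reported only in aggregate
("consistently negative on all methods"), so they are reconstructed: region
`Unlisted`, all labels negative, geometry absent, and Gray units filled with
the deterministic constant 39 — the CT-negative group mean. The constant
fill guarantees all 15 classify negative at the cutoff, which is what exact
reproduction of the classification-level table requires; a truncated-normal
sampler (mean 39, SD 9, upper bound 48) is available when a stochastic fill
is preferred. Stored QLUS labels are kept *and* recomputable from Gray
units; a validation routine cross-checks the two (0 disagreements on the
embedded rows).

Whole-lung rows (RW/LW) stay single rows; no per-lobe expansion is done.

## Diagnostic statistics

- 2×2 metrics by the standard formulas; a metric with a zero denominator is
  reported as undefined (`None`), never as 0.
- Cohen kappa from the marginal-product chance agreement, with the
  conventional qualitative bands (fair .21–.40, moderate .41–.60,
  substantial .61–.80, etc.).
- ROC: thresholds sweep the observed score values under the same strict ">"
  positivity rule as the classifier; AUC by the rank (Mann–Whitney)
  construction with midrank ties; SE by the Hanley–McNeil binomial formula;
  best cutoff maximizes Youden J = Se + Sp − 1, ties broken toward the
  higher threshold (higher specificity). "Assuming a binomial distribution"
  is read as the Hanley–McNeil estimator — the standard interpretation.
- Spearman correlation is tie-corrected (midranks), p two-sided.
- Two-group comparisons use the rank-sum (Mann–Whitney) test — the groups
  compared (CT+/CT−, LUS+/LUS− within CT+) are independent, so the paired
  signed-rank form does not apply; exact null distribution for ≤25
  observations without ties, tie-corrected normal approximation otherwise.
  Signed-rank and Friedman tests are provided for paired/repeated designs.
- Univariate logistic regression by maximum likelihood (IRLS via
  statsmodels). Complete separation is detected up front (disjoint predictor
  ranges) and reported as a flag with the direction of divergence instead of
  a divergent fit; quasi-separation is flagged when the slope or its SE
  blows up. Wald 95% CI and p on the odds-ratio scale; goodness of fit by
  Hosmer–Lemeshow over 10 risk-decile groups (fewer when ties collapse
  quantiles), df = groups − 2.
- No multiple-testing correction is applied, matching the source analysis;
  all p-values are two-sided.
- Rounding for table reproduction is half-away-from-zero at the printed
  precision; means are accompanied by sample SDs (n − 1).

## The synthetic generator

**Image model** (first-order speckle, no wave propagation or beam geometry):

1. Per-pixel amplitude ~ Rayleigh(scale by tissue class): soft tissue above
   the pleura (scale 5), bright pleural band (30, 1 mm thick), dark aerated
   lung below (1.6), consolidation (6), A-line reverberation bands at k ×
   pleural depth with scale 30 × 0.45^(k−1), optional B-line columns (24).
2. Attenuation: amplitude × exp(−0.025/mm × aerated path traversed above
   the pixel). Accumulating the path only through aerated lung is what
   makes a deep consolidation dimmer than a subpleural one of equal size —
   the physical reason visual ultrasound misses non-subpleural pneumonia.
3. Log compression: 20·log10(A/100) mapped from [−45 dB, 0] onto [0, 255],
   quantized to integers.

Default geometry is a 60 × 40 mm frame at 0.2 × 0.25 mm spacing with the
pleura at 15 mm. With these defaults the consolidation-free ROI mean lands
near 40 GU and large subpleural consolidations near 105–130 GU, matching the
study's group locations. The scales were chosen once, by matching those
group means analytically and then numerically; they are not fitted to any
test outcome. A "nonaerated volume" is defined as mask area × a nominal
80 mm slab thickness — there is no 3-D reference here, only the monotone
volume–score relation needs emulating.

**Cohort model.** CT-negative Gray units ~ Normal(39, 9) truncated to
[0, 52] and rounded to integers. The upper bound is the largest CT-negative
value in the printed rows; an untruncated Gaussian tail would put ~15% of
healthy mass above the cutoff, which contradicts the ~95% specificity regime
the method operates in — the bound is a deliberate modeling choice, not a
fit (the bounds are configurable). CT-positive rows draw distance from
pleura (0 with probability 0.6, else Gamma(2, 12) mm), lesion size
(lognormal, median 52 mm) and volume (size × lognormal factor, median 3.4),
then either

- **table mode** (fast): GU = 40 + 95·v/(v + 120) − 0.7·d + N(0, 11),
  clipped and rounded — a saturating monotone volume link minus a linear
  distance penalty; or
- **image mode**: render the frame with the matching consolidation geometry
  and score it with the real quantification operator, so the whole pipeline
  is exercised.

CXR/LUS labels come from logistic links favoring larger and shallower
lesions (LUS logit = 2.5 + 0.02·size − 0.4·distance; CXR logit = −1.0 +
0.03·size − 0.03·distance), with false-positive probabilities 0.2 (CXR) and
0.05 (LUS) on negative rows — the error rates observed in the study's 20
CT-negative hemithoraxes. All randomness flows from a single
`numpy.random.default_rng(seed)` per call; identical config + seed gives
byte-identical images and tables.

**What the generator does *not* emulate:** convex-probe fan geometry, RF
speckle correlation, operator variability, rib shadows, machine-setting
drift, and the per-image variance of real Gray-unit scores (the synthetic
ROI averages tens of thousands of independent pixels, so its scores are far
less dispersed than clinical ones at fixed lesion geometry; cohort-level
dispersion comes from the lesion-geometry distributions). Tests passing on
synthetic cohorts therefore validate the *machinery* — scoring, statistics,
cutoff logic — not clinical performance on real images.

## Reproduction surface and known non-reproducibles

`reproduce_paper()` recomputes the full accuracy table, the Gray-unit group
means (93 / 103 / 73), the lesion-geometry comparisons, correlations,
logistic fits and an ROC block from the embedded cohort; reruns are
byte-identical (the default fill is deterministic). The chest-X-ray
true-negative count follows the running text (16; the table's "6" is
inconsistent with its own specificity .80 and accuracy .69 and with "falsely
positive in 4").

Quantities that are *not* reproducible from the printed rows, and are
reported as caveats instead of results:

- The published ROC (AUC .971, SE .020) and its 95%/90% operating point:
  they depend on the 15 unprinted CT-negative Gray-unit values. On the
  constant-fill cohort the AUC computes to .981 and the Youden-best cutoff
  to 52 (any threshold in [52, 58) gives J = .932 vs .882 at 48) — with 15
  negatives pinned at 39, thresholds just above the lone 52-GU false
  positive dominate. Both numbers are printed with that caveat attached.
- The published QLUS kappa .85: the counts (41, 1, 3, 19) give 0.8584,
  which *rounds* to .86; .85 is a truncation. The computed value is
  reported; tests accept agreement within one printed ulp.
- The combined-method PPV/NPV cells (.85/.75) disagree with their own
  counts (which give .87/.60); the computed values are reported.
- Spearman r = .63/.79/−.77 and the logistic OR 1.08/0.95: the exact row
  sets are unstated, and within the 44 CT-positive rows nonaerated volume
  perfectly separates the QLUS call, so no finite slope exists on that
  subset. Both candidate row sets (CT-positive rows; all rows with a
  printed volume) are computed and reported without asserting equality to
  the printed coefficients.
- The CT-negative mean 39 ± 9 (depends on the same unprinted values) and
  the lobe-localization counts (not derivable from the row table under any
  single whole-lung-row convention).

## Problem sizes in tests

Tests use the embedded 64-row cohort for all exact checks; property checks
use 40–60 random instances for the ROC/metric oracles, 100 replicates at
n = 500 for logistic parameter recovery, 200-row table-mode cohorts for the
correlation-sign and separation checks, and 50 paired seeds of reduced
40 × 20 mm frames for the simulator monotonicity Monte-Carlo — sizes at
which every Monte-Carlo margin in the assertions is several standard errors
wide while the suite stays fast.
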