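# Methods

## Problem and scope

Intraepidermal nerve fibre density (IENFd, fibres per mm of epidermal
length) is the diagnostic gold standard for small-fibre neuropathy, but it
requires manual counting. This package implements an area-based
alternative: segment the PGP9.5-labelled nerve fibres inside a manually
delineated epidermis, sum the calibrated particle area (IENFa, µm²), and
normalise it by the epidermis perimeter (IENFa/P, µm²/µm) or area
(IENFa/A, reported ×100). The package covers the image pipeline (three
segmentation backends, particle gating, biomarker computation), the
validation statistics used to characterise such biomarkers, and seeded
generators that stand in for the unavailable patient data.

## Image model

Images are 2-D, two-channel (nerve = PGP9.5, epidermis = NKCC1) rasters
normalised to [0, 1] by source bit depth, with a calibration `s` in µm per
pixel (default 1.5 µm/px, the reference acquisition setting). Coordinates
are 0-based with pixel centres at integer positions, x = column, y = row.
The epidermis ROI is a simple polygon; its area (shoelace × s²) and
perimeter (edge length × s) come from the continuous geometry — those are
the values a delineation tool reports — while a boundary-inclusive
pixel-centre raster of the same polygon gates the particle analysis. The
inclusive rasterisation over-counts a polygon's area by roughly its
perimeter in pixels, which is negligible for real epidermis ROIs
(thousands of px²) but visible on toy squares; tests therefore check
raster/geometry agreement at realistic sizes.

## Segmentation backends

* **ED (edge detection).** Sobel gradient magnitude √(Gx² + Gy²) using the
  classic 3×3 kernels scaled so a unit step edge responds with 1.0,
  reflected borders, capped at 1. The magnitude is thresholded (numeric in
  [0, 1] or Otsu), then optionally refined by a morphological close (disk,
  radius 1) and hole filling — the minimal reading of "Close" and "Fill
  Holes".
* **CF (custom convolution filtering).** A user kernel applied *without*
  flipping, the convention of common image-processing tools; a delta input
  therefore reproduces the 180°-rotated kernel. Negative responses are
  clipped to zero, responses capped at 1, then the same
  threshold/morphology chain as ED. The default kernel is a zero-mean 3×3
  high-pass (centre 8, neighbours −1), chosen to contrast thin bright
  fibres against background; the kernel actually used in the reference
  workflow was selected by eye and is not published, so this default is a
  declared substitute, configurable via the config file.
* **AA (trainable automated annotation).** A seeded random forest
  (100 trees, unlimited depth) over a fixed 20-feature stack per pixel:
  raw intensity; Gaussian blurs at σ ∈ {1, 2, 4, 8} px; Sobel magnitude of
  each blur; both Hessian eigenvalues per σ; differences of Gaussians of
  adjacent σ. The feature list of the reference tool is not published;
  this stack covers the same Gaussian/edge/curvature families while being
  deterministic. Training scribbles carry a `round` provenance column so
  the correction loop (label mistakes, retrain with the same seed) is
  reproducible. AA classifies the original pixels directly — no image
  transformation is applied.

Manual per-image threshold optimisation is replaced by an explicit numeric
threshold plus an Otsu mode for unattended runs; every CLI run logs the
threshold used.

## Particle analysis and biomarkers

The nerve mask is intersected with the epidermis mask and labelled with
8-connectivity (appropriate for thin diagonal structures). A component is
excluded if (a) any pixel lies on the 1-px inner boundary ring of the
epidermis mask (morphological erosion difference; ring width
configurable), or (b) its calibrated area is below 0.40 µm². The retained
total is IENFa; IENFa/P = IENFa / perimeter and IENFa/A = 100 × IENFa /
area. Subjects average two (or more) sections per metric.

Two deliberate unit notes. First, at the reference calibration of
1.5 µm/px one pixel is 2.25 µm², so the 0.40 µm² filter excludes nothing;
the filter is only active at finer calibrations. Both the threshold and
the calibration are configurable, and the synthetic image generator
defaults to 0.5 µm/px so the filter is exercised. Second, the epidermis
*perimeter* (both surfaces plus lateral ends) is used as the IENFa/P
denominator, treating it as an approximation of twice the epidermal
length; delineating the dermal–epidermal junction alone is out of scope.

IENFd denervation calls use the age-specific cut-offs 5.88 fibres/mm below
age 60 and 2.50 at or above 60, strictly below the cut-off; exactly 60
falls in the older stratum (the published phrasing leaves 60 unassigned).

## Synthetic images

The image generator renders an epidermis band between a smooth upper
border (below an excluded stratum corneum) and an undulating
dermal–epidermal junction (sinusoidal rete ridges of amplitude 12 µm,
wavelength 90 µm, plus smoothed noise). Nerve fibres random-walk upward
from a dermal plexus across the junction, with one optional branch inside
the epidermis; fibre width defaults to 1.5 µm; Gaussian noise targets a
configurable SNR (signal amplitude / noise SD); small background blobs add
clutter. Ground truth (fibre mask, polygon, per-fibre records, fibre
count with the counting rule "intraepidermal branches count once, distinct
dermal parents count separately") is recorded before noise.

One modelling choice matters for interpretation: the intraepidermal fibre
segment is rendered detached from the plexus by a 5-px junction gap. The
thin basement-membrane crossing point is commonly below resolution in real
sections, and without the gap *every* fibre particle would touch the
epidermis-mask boundary ring and be excluded by the periphery rule — which
would contradict the non-degenerate IENFa values the method reports on
real tissue. Truth IENFa is computed with exactly the pipeline's gating
rules (intersection, periphery, minimum area), so end-to-end tests compare
like with like. The generator does not model staining chemistry, a PSF
beyond a small Gaussian blur, 3-D sectioning, hair follicles or sweat
glands; passing its tests shows pipeline self-consistency, not performance
on real histology.

## Synthetic cohorts

Cohorts default to 48 neuropathy / 63 control subjects with truncated-
normal ages (59.3 ± 12.5 and 56.8 ± 13.0 years on [20, 85]) and male
fractions 31/48 and 40/63. Each subject carries a latent innervation
variable L ~ N(0, 1); every biomarker loads on L with ρ = 0.92 (see
below).

* **Controls.** Each biomarker is its target mean plus a centred age
  effect, a centred male-sex effect (IENFd: −1.45; IENFa/A-CF: −0.24;
  other metrics are age-only), and a residual scaled so the marginal SD
  hits the target exactly (7.83 ± 2.94 for IENFd, 1.02 ± 0.49 for
  IENFa/A-AA, and so on). The IENFd age slope is −0.105 fibres/mm/year;
  the other raw slopes derive from standardized coefficients of −0.27
  (area-based) and −0.40 (length-based), reflecting the stronger age
  dependence of length-based metrics.
* **Neuropathy.** Biomarkers are zero-inflated truncated normals: a point
  mass at zero (π = 0.30, completely denervated subjects) plus a
  zero-truncated normal whose parameters are moment-matched numerically so
  the mixture reproduces the target mean and SD exactly (e.g. IENFd
  1.58 ± 1.98). Values are coupled to L through a Gaussian copula, so the
  zeros cluster on the same low-innervation subjects across metrics.
  π below ≈ 0.25 is infeasible for the IENFd target (the zero-truncated
  component would need CV > 1).

ρ = 0.92 and π = 0.30 were fixed at design time against the generator's
calibration targets: pooled r(IENFa, IENFd) ≥ 0.7 in ≈ all replicates, and
mean AUC ≥ 0.91 / mean Youden J ≥ 0.7 for IENFa/A-AA against
denervation-rule labels (measured 0.92 / 0.72 over 100 replicate
cohorts). A known limitation follows: the within-control correlation
(≈ 0.8) is higher than the moderate control-group correlation the method
shows on real data (≈ 0.5–0.6). The two cannot be matched simultaneously,
because labelling by a hard IENFd threshold makes borderline subjects
irreducible label noise; reproducing the diagnostic separation was given
priority. Nerve-conduction amplitudes (sural SNAP 7.5 ± 5.5 µV, tibial
CMAP 11.2 ± 5.3 mV in neuropathy) are noisy increasing transforms of L so
that moderate (r ≈ 0.4–0.6) correlations emerge. Rater readings add a
per-rater bias and measurement noise to a chosen biomarker, with repeats
for intra-rater designs.

All randomness flows from one seed through `numpy.random.default_rng`;
replicate studies derive seeds deterministically from a base seed.

## Statistics

* **ICC**: two-way ANOVA, single measure; absolute agreement by default
  (random rater panel), consistency as an option. Zero subject variance is
  an error, not NaN.
* **Cluster bootstrap comparison**: subjects resampled with replacement
  (default B = 1000); per-replicate ICCs per biomarker; pairwise
  difference distributions give percentile 95% CIs and two-sided tail
  p-values (floored at 1/B), Holm-adjusted across the pair family. Both
  significance rules are reported — the CI-excludes-zero rule and the
  Holm-adjusted p rule — because the published procedure combines them
  without fully specifying the mapping. The Holm-protected family-wise
  false-positive rate is ≈ 5% at the reference design's scale
  (~110 subjects); percentile-bootstrap p-values are mildly liberal for
  much smaller panels.
* **Regression**: OLS with 95% CIs; standardized coefficients from a
  parallel fit with z-scored continuous variables, satisfying
  β_std = β·SD(x)/SD(y) for single terms.
* **Steiger's Z** for two dependent correlations sharing a variable, via
  Fisher transforms and the pooled-r covariance term; inputs implying a
  non-positive-definite correlation matrix are rejected.
* **ROC**: empirical curve over midpoint thresholds with ±∞ sentinels;
  trapezoidal AUC equals the Mann–Whitney pair-counting statistic (ties
  half-weighted) by construction; the biomarker is oriented so AUC ≥ 0.5
  (low value ⇒ disease expected) and the orientation is reported; Youden
  ties resolve to higher specificity.
* **DeLong**: placement-value (structural components) covariance estimate
  for paired AUCs, two-sided normal p.
* **Group comparisons**: Shapiro–Wilk gate (α = 0.05) selecting t-test vs
  Wilcoxon rank-sum; χ² with Fisher's exact fallback when any expected
  cell is ≤ 5 (the ≤ keeps perfectly separated balanced 2×2 tables on the
  exact path); adjusted p from the group term of an OLS model with age and
  sex.
* **CV**: 100 × sample SD / mean.

## Problem sizes in the checks

The acceptance checks use 200 replicate cohorts for calibration/regression
recovery, 100 for diagnostic performance and correlation structure, 1000
replicates for null-uniformity simulations, 100 null studies at B = 500
for the bootstrap family-wise rate, and three 300×600-px sections at
SNR 5 for end-to-end IENFa recovery (train on one section, evaluate on
fresh ones; recovery errors measured ≈ 5%, bound 25%). These sizes were
chosen so Monte-Carlo error is small relative to each tolerance.

## Known limitations

* The CF kernel, AA feature set and forest hyperparameters are declared
  substitutes for unpublished settings, not reconstructions.
* Sections are treated as single 2-D planes; projections of thick
  sections are not modelled.
* The periphery rule excludes junction-crossing particles unless the
  crossing point is sub-resolution (see the junction-gap discussion); on
  real data the effective behaviour depends on how fragmented the
  segmentation is at the junction.
* The cohort generator reproduces marginal group distributions, effect
  sizes and pooled correlation/diagnostic structure, but overstates the
  within-control correlation (above) and contains no biochemical
  covariates.
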