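# Methods

This note documents the models, conventions and numerical choices behind
`aesthstat`, the assumptions they rest on, and what the synthetic-data
tests do and do not establish about real image corpora.

## Color representation

**Cone excitations and scaling.**  Images are assumed sRGB-encoded and
are linearized before any conversion; all chromatic statistics operate
on linear light.  The default RGB→LMS matrix is the standard sRGB→XYZ
matrix composed with the Hunt–Pointer–Estévez XYZ→LMS matrix, with the
three cone rows rescaled so that the equal-energy stimulus
(XYZ = (1,1,1)) maps to luminance L+M = 1 and chromaticity
(l, s) = (0.70, 1.0).  That white-point convention anchors all
hue/saturation geometry, so the package fixes it exactly rather than
inheriting whatever scale a fundamentals table happens to use.  A
spectral path (`cone_fundamentals`, `lms_from_spectrum`) supports
calibration from radiance spectra by 1-nm summation; the shipped cone
sensitivity curves are smooth log-Gaussian approximations (synthetic,
as labelled in their docstring) — any reasonable fundamentals yield the
same chromaticity convention after the equal-energy calibration, which
is the property downstream statistics depend on.

**Dark-pixel exclusion.**  Chromaticity is a ratio and becomes
noise-dominated at low luminance, so pixels with L+M < 0.00045 (in
units where the equal-energy white has L+M = 1) are excluded from every
statistic involving l, s, saturation or hue.  The threshold is strict
(`<`) and configurable; luminance moments use all pixels.  The absolute
radiance scale of a display is not recoverable from image files, so the
unit convention above is the only meaningful interpretation offered.

**Hue convention.**  Hue is measured counterclockwise from the +l
("red") direction, in [0°, 360°); the eight hue segments are 45° wide
and centered at k·45°.  Segment statistics exclude pixels with
saturation < 0.05, preventing near-white pixels from being arbitrarily
assigned a hue.  Empty segments report missing values, not zeros — a
zero would conflate absence of pixels with zero saturation.

**CIELUV.**  The chromatic-contrast statistic is the RMS distance of
each pixel from the image's mean chromaticity in the (u\*, v\*) plane
(L\* excluded), relative to the equal-energy white by default.  The
formulas are the CIE 1976 definitions, cross-checked in the test suite
against scikit-image's implementation under a D65 white.

## Chromatic distribution ellipses

Standard-deviation ellipses are eigen-decompositions of the 2-D sample
covariance of the pixel chromaticities (sample SDs, n−1 denominator
throughout the package).  Elongation is computed in the
variance-normalized diagram — each axis divided by that image's own
pixel SD — as log(SD along the −45° diagonal / SD along +45°), natural
log.  Normalizing first makes the measure scale-free: a perfectly
isotropic cloud gives exactly 0, clouds elongated along the natural
(blue–yellow) axis give positive values.  The ellipse angle is reported
from the un-normalized covariance, as the major-axis eigenvector angle
in (−90°, 90°], and is flagged undefined for circular clouds.  Whether
ellipse "axis lengths" are 1·SD or 2·SD is immaterial for both
measures, which are ratios or angles; 1·SD is used.

## Spatial statistics

**Spectral slope.**  The 2-D FFT amplitude spectrum is rotationally
averaged into 20 log-spaced frequency bins and a least-squares line fit
to log amplitude vs log frequency over 10 cycles/image up to
half-Nyquist.  The lower cut avoids DC leakage, the upper cut avoids
corner anisotropy of the square spectral support.  No window is applied
by default (a Hann option exists); the planted-exponent recovery tests
(±0.05 across β ∈ {−0.5, −1.0, −1.5}) run without one.

**Fractal dimensions.**  The 1-D dimension box-counts the binary edge
map (Canny, σ = 1, hysteresis at the 70th/90th gradient-magnitude
quantiles) over dyadic box sizes; estimates outside [1, 2] are clipped
with a warning.  The 2-D dimension uses differential box counting on
the intensity surface with two refinements adopted after checking the
estimator against analytic fixtures: the box height scales with s − 1
(an s-pixel block spans s − 1 sample intervals), and the per-block
count is the continuous max(span/height, 1) rather than an integer
ceiling.  The naive variant is biased toward 2 on smooth and weakly
rough surfaces (planar ramp: 1.89; fBm H = 0.5: 2.20 where 2.5 is
correct); the refined variant gives 2.00 and ≈ 2.39.  A residual
downward bias on fBm surfaces remains — differential box counting
compresses the (2, 3) range — and is documented rather than hidden:
the fixtures bound it at ±0.15.

**Lacunarity.**  The luminance channel is binarized at its mean and
gliding-box masses computed by integral image; Λ(r) = ⟨m²⟩/⟨m⟩² ≥ 1 by
Jensen's inequality, with equality on translation-invariant fields.
The scalar summary is the mean of ln Λ(r) over dyadic r from 2 to H/4
(0 for homogeneous fields).  Binarization threshold and aggregation are
package choices; both are exposed.

**Entropy.**  Shannon entropy in bits of the 256-level histogram of the
min–max rescaled channel: 0 for constant images, 8 for a uniform
histogram.

**Straight vs non-straight edges.**  Edge pixels within 1 px of a
probabilistic-Hough segment count as straight, the rest as non-straight;
densities are normalized by total pixel count.  The minimum segment
length is 0.15·min(H, W): a chord much shorter than that stays within
1 px of a large circular arc (its sagitta is below the tolerance), so
smaller minima silently absorb curves into the straight class.

**Gabor edge density.**  The gamma-encoded image is collapsed to
ITU-R 601-2 luma (the convention of the edge-statistics literature,
deliberately not linear light), filtered with 24 odd-phase Gabor
kernels (7.5° steps spanning 180° of orientation, i.e. a full rotation
of edge polarity; 8 cycles/image; ~1 octave bandwidth; isotropic
Gaussian envelope with orientation-independent square support), and the
per-pixel maximum over orientations is averaged.  Convolution is cyclic
on the mean-subtracted image: zero-padding would hand a constant image
a spurious boundary response and break contrast linearity.

**Edge-orientation entropy.**  First order: Shannon entropy of the
24-bin orientation histogram over edge pixels.  Second order: the
10,000 strongest edge pixels are compared pairwise; orientation
differences (folded to [0°, 90°]) are histogrammed within 12
log-spaced distance bins from 2 px to half the image diagonal, and the
per-bin entropies averaged.  Parallel structure drives the measure to
0; independent random orientations approach the histogram maximum (the
fold makes the two extreme difference bins half-width, so the
attainable maximum is slightly below log₂ of the bin count — the tests
account for this).

**PHOG.**  Gradient orientation histograms (16 bins over 180°,
magnitude-weighted) on a pyramid of the whole image and 2×2, 4×4, 8×8
grids.  Self-similarity is the mean histogram intersection between each
sub-region and the whole image; anisotropy is the variance of the
normalized orientation-bin strengths at the finest level; complexity is
the mean gradient magnitude.  Constant channels give complexity 0,
anisotropy 0 and undefined self-similarity.

**Channel assignment.**  Spectral slope, fractal dimensions, entropy,
edge densities and PHOG run on luminance and both cone-opponent
channels; lacunarity on luminance only; Gabor edge density and both
EOE orders on the luma grayscale only.  With the chromatic set this
gives the 58 per-image statistics.

## Behavioral design and aggregation

A subset of k images (default 10) is shown in all C(k, 2) pairs — 45
trials at k = 10 — with per-trial random left/right placement and
seeded order shuffling.  Trials last 5 s (used as a validation bound).
Looking aggregates as per-infant per-image mean over observed trials
(skipped trials are absent from the denominator, never zero-filled),
then an unweighted mean across infants.  Choices aggregate as per-adult
per-image chosen proportion, then a mean across adults; trials without
a recorded choice are dropped from numerator and denominator, since a
forced-choice trial without a response is a recording failure.  For a
single adult completing the full design the subset scores average
exactly ½.  Score–score association is the Pearson correlation with
the two-sided t-based p-value.  How a 40-image set is partitioned into
subsets across participants is a user-supplied assignment; the
synthetic generator partitions by seeded shuffle into consecutive
blocks and assigns participants round-robin so every image is covered.

## Preference models

All modelling is on z-scored columns (sample SD); z-scoring puts
predictors and outcome on one scale so standardized coefficients are
comparable.

**Screening.**  A feature is excluded before regression only when its
apparent univariate relationship with the outcome hinges on a single
observation: some observation has Cook's distance > 4/n, the feature is
significant (α = 0.05) with that observation included, and deleting it
removes the significance or flips the coefficient sign.  A symmetric
"significance flip" rule was rejected: it also flags pure-noise
features whose p-value happens to sit near α.  Every removal is
reported with its diagnostic.

**Backward elimination.**  All predictors enter; the predictor with the
largest coefficient p is removed while any p > 0.1; then the
highest-VIF predictor is removed (refitting, and re-checking p-values)
until all VIF < 1.25.  VIF_j = 1/(1−R²_j) from the auxiliary regression
of predictor j on the others; it equals the diagonal of the inverse
correlation matrix on full-rank inputs (asserted to 1e-8 in the tests).
A forced-entry corroboration path prunes all non-contributing
predictors per refit instead of one at a time; on the synthetic
recovery suite both paths terminate in the same predictor set.  When
the feature count reaches n − 1 the initial model cannot be fit
meaningfully, so predictors are pre-ranked by univariate |r| with the
outcome and the top n/2 enter; entering the maximal n − 2 would leave a
single residual degree of freedom and arbitrary p-values, which defeats
p-driven elimination.  This pre-reduction is a package decision — with
58 statistics and 40 images some reduction is unavoidable, and the
choice is flagged here because it can matter.

**PLSR.**  PLS1 via NIPALS, written in-package so that the k-component
model is an exact truncation of the (k+1)-component one — the property
that makes per-permutation cross-validated component re-selection
affordable — and verified coefficient-for-coefficient against
scikit-learn's `PLSRegression` in the tests.  The component count is
selected by leave-one-out cross-validation with the one-standard-error
rule: the smallest count whose mean squared LOO error is within one
standard error of the minimum.  Plain argmin of PRESS systematically
overfits by one to two components on planted two-factor data.  VIP
scores use the standard weighted-sum-of-squared-weights formula, so
mean(VIP²) = 1 exactly; features with VIP > 1.25 are flagged important,
with the relationship sign taken from the model coefficients.

**Permutation null.**  The outcome vector is shuffled (multiset
preserved), the component count re-selected by LOO CV per permutation,
and the selected model's in-sample percent variance explained recorded;
the summary reports the null mean, SD, range, the observed value's z,
and an add-one empirical p = (1 + #{null ≥ obs})/(1 + N), which cannot
be exactly zero at finite N.  All randomness flows from a single named
seed.

A Bayesian regression variant (JZS-prior Bayes factors) is deliberately
not implemented; it is an off-the-shelf computation orthogonal to this
pipeline's machinery.

## Synthetic data: what it emulates and what it does not

Images are built from random-phase fields with planted amplitude
exponents: luminance from one field, chromaticity from two fields mixed
by the Cholesky factor of the requested (l, s) covariance and
orthogonalized sample-wise (steep-spectrum fields have few effective
degrees of freedom, so raw independent draws can be strongly
sample-correlated).  The corpus generator varies exponent, chromatic
offset/spread (mostly along s, where the RGB gamut is wide, with the
negative l–s correlation typical of natural scenes) and luminance
spread across images.  Behavioral tables derive from a planted latent
value per image — a linear combination of z-scored statistics plus
Gaussian noise — through a truncated-Gaussian looking model (baseline
2.5 s, per-trial SD 0.8 s, bounded to [0, 5] s) and a Bradley–Terry
logistic choice model (slope 1.5 on the latent difference).  Those
response-model parameters are package choices exposed on
`BehavioralSpec`.

These generators produce Gaussian textures, not paintings: they have no
objects, compositional structure, brush texture, straight contours
(straight-edge density is typically zero and is dropped as
zero-variance by the model stage on such corpora) or semantic content.
Passing tests therefore establish that the estimators recover what was
planted and that the modelling machinery behaves as specified — not
that any particular statistic predicts human preference for real art.
The study-scale end-to-end test uses 40 images at 550×550 with a
1000-permutation null; unit tests use 64–256 px images and 50–1000
permutations, sizes chosen to exercise the same code paths at desk
scale.

## Known limitations

- The 2-D fractal estimator retains a downward bias of roughly 0.1 on
  mid-range fBm surfaces (see above).
- The mapping between hue-segment labels used in figure annotations of
  the wider literature and this package's angular convention is not
  fixed; segments are named by their center angle in the convention
  stated here.
- The gamut-rescaling helper takes an abstract in-gamut predicate; no
  display-specific calibration (measured primary spectra) is included.
- Second-order EOE caps at the 10,000 strongest edge pixels; an
  all-pairs computation over a 550² edge map is quadratically larger
  for no measurable change in the statistic on tested corpora.
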