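# Methods

## The pipeline

The package decides whether two labeled color-pattern classes are
visually distinguishable without reference to any particular observer's
color perception. The procedure is: (1) standardize each photograph
against an in-frame white reference and crop to the body; (2) encode
the image as a visual signature — a vector of maximal similarities
between stored templates and the image's C1 representation; (3) score a
pair of classes by the leave-one-out success rate of a linear
maximum-margin classifier on the signatures; (4) attach a significance
level by recomputing the whole leave-one-out loop under random label
permutations.

### White-standard calibration

The model is a per-channel linear gain (white-patch model):
`g_c = white_c / mean_c(reference region)`, applied to every pixel and
then clipped to [0, 1], with no offset term. All arithmetic is on
gamma-encoded sRGB values in [0, 1]; no transfer-function linearization
is attempted, matching how this family of descriptors is normally run
on developed images. Calibration is idempotent when the reference patch
is homogeneous (after the first pass the patch sits exactly at the
target, so the second gain is 1); with a heterogeneous patch, clipping
inside the patch can shift its mean and idempotence holds only
approximately. Coordinates are 0-based, row-major, half-open
everywhere.

### Channel maps

*Grayscale pathway*: BT.601 luma, L = 0.299 R + 0.587 G + 0.114 B. The
weights are a design choice (the classical descriptor-literature
default); any fixed convex weighting would preserve the pathway's
defining property, invariance to chroma changes at constant luminance.

*Color pathway*: eight single-opponent channels. For each pair (P, Q)
in {(R, G), (Y, B), (R, C), (Wh, Bk)} with Y = (R+G)/2, C = (G+B)/2 and
Wh = Bk = L, the signed response is

    S = Gauss(σ_center) * P − Gauss(σ_surround) * Q,

and the two channels of the pair are max(S, 0) and max(−S, 0)
(half-wave rectification into complementary non-negative maps, which
jointly carry |S|). Defaults: σ_center = 1 px, σ_surround = 3 px on the
resized image. Note that on a uniform colored field S equals the
constant P − Q — single-opponent cells respond tonically to full-field
color; only the white/black pair (a luminance difference-of-Gaussians)
vanishes there.

### C1 and templates

Gabor parameters follow the published HMAX defaults: 16 scales with
filter sizes 7, 9, …, 37 px, per-scale wavelengths 3.5–22.8 and
envelope widths 2.8–18.2, aspect ratio 0.3, four orientations
(0°/45°/90°/135°, indexed by the orientation of the bar detected).
Filters are zero-mean, unit-norm, on circular support; responses are
absolute values of 'same'-mode correlations (no contrast
normalization, so responses scale linearly with image contrast).
Adjacent scale pairs are max-pooled into 8 bands; each band is
spatially max-pooled over neighborhoods of 8–22 cells and subsampled at
half the neighborhood size.

Templates are patches of the C1 representation (all orientations, and
all channels in color mode) sampled uniformly over every (image, band,
location) at which the patch fits, split equally over four spatial
extents (default 4, 8, 12, 16 C1 cells). Sampling from the full corpus
— including images later used as test folds — reproduces the original
protocol, in which the dictionary is a preliminary step; passing only
training images to `SignatureExtractor.fit` gives the strict
leakage-free variant. The C2 value for a template is
`exp(−d²/(2σ²))` with σ² equal to the patch dimensionality, maximized
over bands and locations. The search uses the inner-product expansion
of the squared distance for speed, then re-evaluates the winning
location by direct subtraction, so the reported value is identical to
an exhaustive scan.

### Classification and significance

The classifier is a linear soft-margin SVM (libsvm via scikit-learn)
with C = 1 and tolerance 1e-6; ties at decision value exactly 0 go to
the lexicographically first class. By default every training fold is
z-scored per coordinate before the fit (the same affine map is applied
to the held-out sample). This is a deliberate addition to the bare
margin contract: Gaussian max-similarity features concentrate near 1
with a spread that depends on image size and template dimensionality,
and a fixed-C margin is meaningful only relative to feature scale — at
desk-scale image sizes, the raw-feature margin collapses to a majority
vote even for cleanly separated classes. Per-fold standardization pins
the scale without leaking test information; `standardize=False`
restores the raw behavior.

The permutation test shuffles the label vector uniformly and recomputes
the full LOO loop per replicate (the same pipeline that produced the
observed statistic — the strictly correct, costlier reading; there is
no approximate mode in the default path). The P-value is the add-one
estimator (1 + b)/(m + 1), never zero and conservative at any m. With
very small balanced groups the identity and label-swap permutations
reproduce a perfect observed rate, so the attainable P at n = 5 + 5 has
expectation ≈ 0.013 even for perfectly separated classes; group sizes
of 8+ per class make this negligible. Multiple testing across a
pairwise grid uses Holm's step-down procedure (note that ordered
p-values (0.001, 0.02, 0.04) at α = 0.05 are *all* significant under
Holm: thresholds 0.0167, 0.025, 0.05).

Templates are not resampled inside LOO folds by default (the dictionary
is a preliminary step); coupling template sampling into the folds is
available by refitting the extractor per fold.

### Field statistics

- 2×2 chi-square: closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), no
  continuity correction (the uncorrected statistic is what the field
  count tables print); p from χ²₁. Fisher's exact test available for
  small cells.
- Exact binomial tail: P(X ≥ k) under Binomial(n, p₀); 9 wins of 11 at
  p₀ = ½ gives 67/2048 ≈ 0.0327.
- Logistic regression: plain maximum likelihood (Newton, tolerance
  1e-8), per-term likelihood-ratio χ²₁ by explicit full/reduced refits.
  No random-effects/GEE machinery: a grouping variable such as year can
  only enter as a fixed covariate, a documented simplification (the
  original analysis added year as a random effect with an unstated
  working-correlation structure, which cannot be replicated faithfully).
  Perfect separation and rank deficiency raise explicit errors.
- One-way ANOVA with Tukey–Kramer HSD (studentized range, unequal n).

## Synthetic data

The image generator does not attempt photorealistic animals; it
reproduces the axes that define the pattern taxonomy — base color,
stripes, blotches — plus overall brightness, on an elongated elliptical
body (aspect 1.7) over a neutral ground, with a white reference strip
along the top edge so calibration is exercised end to end, and a global
illumination gain (default U(0.85, 1.0)) that calibration undoes.
Within-class variability enters through hue jitter (sd 0.02),
stripe/blotch placement jitter (sd 0.03 body fractions) and per-pixel
Gaussian noise (sd 0.02). No quantitative description of real
within-class variability was available; these defaults are calibrated
only so that the pipeline's positive and negative controls behave as
controls, and are documented as arbitrary. The `separation` parameter
linearly scales every between-class spec difference about the mean
spec: 0 collapses the classes (labels carry no visual information — an
exact null), 1 is the nominal palette, 2+ exaggerates. All randomness
derives from one seed through spawned substreams.

The default six-class palette spans plain brown, laterally striped
brown, blotched brown, bright-striped brown, bright high-contrast
green, and plain green bodies; the names are configurable labels.

The metadata generator draws month uniformly on {5, …, 10}, SVL from a
truncated normal (mean 10 cm, sd 2, bounds 5–16) and colors each
individual brown with probability logistic(−0.23 + 0.416·month −
0.289·SVL) — by default the reported male coefficients, with the
intercept set so that about half the simulated animals are brown.
Months are integers and SVL is in centimeters; the recovery
simulations are internally consistent under this convention.

What passing tests on synthetic data do *not* show: that the descriptor
separates real animal patterns photographed under field conditions
(pose variation, occlusion, specularity, background clutter are absent
from the generator), nor that the desk-scale profile reproduces the
published full-scale success rates. Those require the externally
archived photograph corpus (`patdist.dryad.run_reference_corpus`).

## Problem sizes and numerical choices

Desk-scale defaults: images are downsampled so the longer side is at
most 256 px (anti-aliased resampling), 200 templates; the original
protocol (full resolution, 1000 templates, 10,000 permutations) is
reachable through the same parameters. The package's own control
experiments use: positive control at 128×128, 10 images/class, 200
templates, 199 permutations; null calibration at 64×64, 100 templates
(sizes 2/4/6/8 over an 8-scale bank), 99 permutations, 20 replicate
datasets; type-I calibration at the signature level with 60 replicates;
separation-monotonicity at 56×56 with an 8-scale bank, 3 separation
levels × 20 seeds. The parameter-recovery simulation uses 200
replicates of n = 148.

Degenerate inputs are rejected rather than guessed at: classes with
fewer than 2 members, permutation counts below 99 (p-grid too coarse),
reference regions with a zero channel mean, template extents that fit
no C1 map, saturated hue rotations that leave the RGB gamut.

## Known limitations

- The opponent-channel constants, orientation count, similarity width
  and resize policy are all config-exposed defaults, not values fixed
  by the original study; conclusions at full scale could in principle
  shift under variations, which is why every run logs its resolved
  configuration.
- Primate-style opponency is an assumption; a tetrachromatic receiver
  could weight patterns differently.
- Leave-one-out with templates sampled from all images is mildly
  optimistic; the strict mode exists but is slower and was not used for
  the control experiments.
- ML logistic estimates at n = 148 carry a small upward finite-sample
  bias in coefficient magnitude (visible as mean recovered coefficients
  ~3% above the generating values), which is expected behavior, not a
  defect.
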