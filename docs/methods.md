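# Methods

## The measurement problem

In en-face OCT angiography of the peripapillary region, the
choriocapillaris appears as a bright, finely speckled flow signal.  Local
loss of that signal — *microvascular dropout* (MvD), also called a flow
void — shows up as a contiguous dark patch, almost always inside the
zones of peripapillary atrophy (PPA) that ring the optic disc: the
beta zone adjacent to the disc (RPE absent) and, peripheral to it, the
alpha zone (irregular RPE).  `mvdquant` quantifies dropout on such
images and aggregates per-eye measurements into cohort statistics for a
two-group myopia design (high myopia, SE ≤ −6.0 D, versus mild-to-moderate
myopia, −6.0 D < SE ≤ −0.5 D).

## Detection rule

The detector is deliberately simple and fully parameterized:

1. **Large-vessel exclusion.**  Bright connected components
   (grey ≥ `vessel_bright_threshold`, default 180) whose skeleton length
   is ≥ `vessel_min_length_px` (30) and whose mean width
   (area / skeleton length) is ≥ `vessel_min_width_px` (4) are marked as
   large choroidal vessels.  Their pixels are *invalidated*, not
   inpainted: synthesizing grey values would feed the threshold rule
   below.  The elongation requirement protects compact bright speckle
   from being masked.  Scope is image-wide by default
   (`vessel_masking_scope`), switchable to zones-only.
2. **Dark thresholding.**  A pixel is dropout-eligible when it is valid
   (not vessel) and its grey value is *strictly* below `grey_threshold`
   (default 50 on the 8-bit scale).
3. **Zone restriction and labeling.**  Eligible pixels are clipped to the
   PPA union (alpha ∪ beta) *before* connected-component labeling
   (default `clip_before_label`; the alternative order is one flag away).
   Clipping first means a dark structure outside the zones — the disc
   itself, for instance — can never merge with in-zone dropout.
   Connectivity is 8 by default (dropout blobs are irregular; diagonal
   contact reads as contiguous), 4 available everywhere.
4. **Area filter.**  Components with pixel count *strictly* greater than
   `min_area_px` (default 20) survive.  Both inequalities are strict by
   design; both constants are configuration.
5. **Zone assignment.**  Each region is assigned to the zone holding the
   majority of its pixels; an exact tie goes to beta, the primary zone of
   the analysis.

Areas are exact: `area_mm2 = area_px × pitch²`, with the default pitch of
11.25 μm (a 4.5 mm field sampled by 400 clusters), i.e. 126.5625 μm² per
pixel.  Images of other sizes are accepted only with an explicit pitch.

Flow density of a zone is reported as the count of valid zone pixels with
grey ≥ `signal_threshold` (default 50), plus a fraction normalized by the
zone's pixel count.  Density and the alpha-zone sub-analysis are verified
by internal properties only (additivity, complementarity when no grey
value equals the threshold, monotone decrease under vessel exclusion) —
they are not tied to any external reference values, whose units are not
well defined.

## Cohort statistics

Eyes pass quality control when the scan quality score is ≥ 6/10 and no
artifact flag (double-vessel pattern, motion, segmentation error over
three lines) is present.  Groups are compared with the two-sided
independent two-sample t-test (Student by default, Welch optional);
rank association uses Spearman correlation with average ranks for ties;
dropout prevalence is the fraction of eyes with at least one detected
region.  The dropout-area model is reported two ways: per-predictor
simple linear fits (signed Pearson r with its p-value) for age, SE, AL
and beta-zone area, and a joint OLS fit of all four predictors with a
condition-number collinearity warning.  Eyes are analysis units; no
multiple-testing correction is applied; eyes without dropout contribute
zero area to group means and are counted separately in prevalence.

## Synthetic cohort generator

No patient data accompany the package, so the generator is the test bed
for every stage.  Per eye it renders a 400×400 8-bit image: correlated
speckle background (smoothed white noise, default mean 160, SD 25,
correlation length 2 px, truncated below at grey 60 so texture alone can
never cross the dark threshold), a dark disc (grey 25, radius ≈ 55 px),
bright vessel trees (random-walk trunks with branches, grey 200–240,
width 4–8 px), a beta ring 4-connected-adjacent to the disc, an optional
alpha ring peripheral to it, and dropout blobs planted last so every
planted pixel is strictly below 50.  Blobs are grown by stochastic
4-neighborhood breadth-first growth to an exact pixel budget, with a
1-pixel exclusion buffer around the disc and around other blobs so
planted regions never merge.  By construction, on vessel-free renders the
detector recovers planted truth pixel-for-pixel, and with vessels enabled
it can only lose area (bright vessels never overlap dark blobs) — both
properties are tested, not assumed.

### Covariate model

Per group (profile):

* SE and age: truncated normals; the pre-truncation location is solved so
  the *truncated* mean equals the documented group mean (−7.14 D / −2.51 D
  for SE).  The printed age dispersion (SD ≈ 13–14 y inside an 18–40 y
  window) cannot be literal moments of any distribution on that interval;
  it is treated as the scale parameter of the truncated normal.
* AL = group mean + slope·(SE − group mean SE) + residual, slope
  −0.35 mm/D (a typical refraction/axial-length slope), residual SD solved
  so the total group SD matches the documented 0.88 / 1.15 mm.
* True beta-zone area: linear in SE and in the AL residual plus truncated
  normal noise.  The AL-residual loading is what lets the cohort-level
  r(AL) and r(SE) be matched *simultaneously*; with SE as the only driver
  the two correlations are rigidly linked through the AL model.
* Dropout: present with per-group probability (0.99 high, ≈0.917 mild,
  pooling to 95.1%); when present, total beta-zone dropout area is
  `coeff · beta_area^power` times a mean-one multiplicative noise drawn
  from a ±2σ-truncated log-normal.  The convex power coupling is the
  simplest monotone device that lets the beta-area correlation be tuned
  independently of the group means; the truncation keeps single eyes from
  dominating a 100-eye cohort mean.  The total is split into 1 + Poisson
  regions of ≥ 21 px each.  With profile probability an additional blob is
  planted in the alpha ring.

All constants live in the versioned YAML profiles
(`src/mvdquant/profiles/*.yaml`), not in code.

### Calibration

The free constants (beta-area location, dropout coupling coefficient per
group; coupling power, SE/AL loadings, mild-group beta SD and noise width
shared) were calibrated against the documented cohort targets — group
means of dropout area (0.248 / 0.089 mm²) and beta-zone area
(1.221 / 0.562 mm²), pooled prevalence (95.1%) and the pooled
dropout-area correlations with beta area (0.894), SE (−0.484) and AL
(0.477) — by nested Monte-Carlo root finding at n = 4·10⁵ eyes per group
(secant iteration for the means inside a least-squares solve for the
correlation knobs).  Calibration is population-level: no constant was
chosen with reference to any particular cohort seed.

The documented group SDs of dropout and beta-zone area are *not*
calibration targets: given the printed group means, those SDs are
mutually inconsistent with the printed pooled correlation r = 0.894 (the
implied within-group coupling would force a dispersion the mild group
cannot carry while staying positive).  Realized SDs land near, but not
at, the printed values.

### Sampling design

A study-sized cohort (95 + 110 eyes) is a small sample for correlation
statistics: with iid draws the sampling SD of r(SE) at n = 205 is ≈ 0.05
and of the mild-group dropout mean ≈ 17% of its value, i.e. cohorts from
a perfectly calibrated model would still scatter far around the targets.
The generator therefore samples each latent dimension by stratified
inverse transform (Latin-hypercube: one draw per equal-probability
quantile band, randomly ordered) and applies Iman–Conover rank
decorrelation across the latent matrix, which suppresses spurious sample
correlation between independent latents while leaving every marginal
exactly stratified.  Population distributions are unchanged; finite
cohorts are simply *representative* of them.  Consequences worth knowing:
draws within one cohort are not mutually independent (means are
over-dispersed-free), so the generator is a test bed for estimators of
location and association, not for studying iid sampling error.

### What the generator does not emulate

Physical OCT speckle statistics, projection and motion artifacts, disc
tilt and optical magnification effects of long eyes, spatial
heterogeneity of dropout within the ring, inter-eye correlation within
subjects (one eye per synthetic subject), and any glaucoma-related
structure.  Passing tests demonstrate that the *pipeline* measures what
it claims on data whose ground truth is known — not that the detection
rule is clinically optimal on real angiograms.

## Numerical choices and degenerate inputs

* Grey scale is fixed 8-bit; other depths are rejected, never rescaled —
  silent rescaling would shift the threshold-50 rule.
* Masks must be exactly {0, 255}; anything else errors (ambiguous
  semi-transparent exports).
* Zone masks must be pairwise disjoint; overlap is an error, not a
  silent resolution.
* An empty zone yields density 0 with an explicit empty-zone flag.
* Constant input to a correlation raises rather than returning 0.
* A group with fewer than two eyes cannot be compared; fewer than ten
  eyes cannot be regressed.
* Region sorting is deterministic: area descending, ties by centroid.
* Dropout blobs that cannot be placed after bounded retries raise a
  generation error naming the eye.

## Problem sizes

The packaged profiles generate the full 95 + 110 eye study in ~10 s on a
single core (rendering dominates).  The acceptance computation runs the
complete rendered-pixel pipeline on those 205 eyes; calibration-check
tests use 2 000–10 000 covariate-level draws, which are pixel-free and
effectively instant.
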