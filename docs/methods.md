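# Methods

## The verification problem

One-to-one biometric verification over muzzle-pattern photographs: given
two images, decide whether they show the same animal. Performance is
summarized by the ISO-style rates — TMR/FNMR over genuine pairs (same
individual), TNMR/FMR over imposter pairs (different individuals),
accuracy over all pairs, and FTA for capture attempts whose images are
unusable for matching. The deployment scenario is harvest registration:
every false match is an animal wrongly flagged as already registered, so
the operating point is chosen to drive false matches to zero on a
calibration set.

## Synthetic population model

Real harvest photographs are not distributable with the package, so the
generator (`muzzleid.synthetic`) emulates the statistical structure of a
harvest-record database rather than its photographic appearance.

**Identity.** Each animal's base pattern is a seeded centroidal Voronoi
tessellation: 250 plaque sites, two Lloyd relaxation iterations, plaques
with per-plaque random albedo (0.55–1.0) separated by valley grooves 3 px
wide, two dark nostril ellipses with per-individual jittered geometry, and
an identity-static smoothed speckle field (±22% multiplicative) so plaque
interiors carry texture rather than being flat. Intensities span exactly
the `contrast` parameter (default 0.7) of full scale. The pattern is a
pure function of the identity seed; distinct seeds give distinct
tessellations.

**Capture.** A photograph warps the base pattern into a 960 × 720 frame
(in-plane rotation jitter ~N(0, 1.2°) clipped at ±3°, translation ±10 px;
the overhead view applies a fixed projective foreshortening with vertical
scale 0.68 and top-edge taper 0.84), composites it over seeded
low-frequency background clutter, then degrades: occlusion blobs over the
muzzle, multiplicative illumination tilt, Gaussian blur, additive sensor
noise. All perturbations are deterministic given the capture seed. The
ground-truth annotation is the bounding rectangle of the warped pattern
plus the two rendered nostril circles.

**Quality tiers.** The field protocol grades images manually; here the
tier is a deterministic monotone function of the capture parameters:
*high* iff blur ≤ 0.8 px, occlusion ≤ 5%, |tilt| ≤ 0.3; *unusable* iff
blur ≥ 3 px or occlusion ≥ 40%; *medium* otherwise. Tier-conditional
parameter ranges are constructed to grade back to the intended tier.

**Population shape.** Individuals receive 2 images (p = 0.75) or 3
(p = 0.25) — mean 2.25, matching a many-individuals/few-images database of
~2.26 images per animal. Under the paired protocol the first capture is
frontal, the second overhead, the third (when present) frontal again. The
per-capture tier mix defaults to high 0.55 / medium 0.406 / unusable 0.044
(the unusable share mirrors a field campaign where ~4.3% of submissions
fail acquisition); captures of one animal share a session tier with
probability 0.8 (independent redraw otherwise), which leaves the marginal
mix unchanged while giving the within-individual quality correlation a
single photo session produces. A `noiseless` preset zeroes every
perturbation, giving the perfectly separable limit used as a pipeline
sanity bound.

**What the generator does not model** — and hence what passing tests do
not show about field data: photorealistic skin appearance, post-mortem
tissue changes, dirt that survives cleaning, skin disease, specular
highlights, perspective beyond the fixed overhead homography, or
annotation error (annotations are exact by construction). Results on
synthetic data bound the pipeline's logic, not field accuracy.

## Preprocessing

Greyscale luminance (BT.601 weights) → anisotropic bilinear resize to
480 × 640 (width × height, no aspect preservation) → intensities on
[0, 1] → `z = (x − 0.485)/0.229`. The normalization constants are applied
as a fixed affine map (the canonical single-channel pretrained-backbone
constants), not per-image moment matching; a config switch provides the
per-image variant for sensitivity analysis. The resampling kernel is
bilinear by choice; nearest/bicubic are config options.

## Matcher

The built-in matcher reproduces the coarse → fine → match → refine control
flow of detector-free learned matchers with classical normalized
cross-correlation, keeping the pipeline deterministic and free of learned
weights (an external pretrained matcher can be plugged in through
`ExternalMatcherAdapter`, which enforces the same contract).

- **Coarse.** 8 × 8 cells (60 × 80 grid), zero-mean unit-norm cell
  descriptors, cells with variance < 1e-4 excluded as flat. A cell pair is
  kept iff each is the other's best correlation within a ±10-cell search
  window and the correlation reaches 0.6. Implemented as a loop over the
  441 cell displacements with running per-cell maxima — equivalent to the
  full masked correlation matrix at a tenth of the cost.
- **Fine.** Each candidate is re-localized by correlating a 16 px patch
  over ±4 px integer offsets; kept iff the peak reaches 0.7.
- **Consensus.** Inliers lie within 12 px of the component-wise median
  displacement — a deterministic robust filter in place of randomized
  sample consensus, chosen so the whole match is seed-free.
- **Score.** `similarity = n_inliers / min(candidate cells)`, candidate
  cells being valid cells whose centre is at least 12 px
  (`fine_window/2 + fine_search`) from the border — cells closer than that
  can never survive refinement, and excluding them is what lets a perfect
  self-match reach similarity exactly 1. Both the normalized similarity
  and the raw inlier count are reported; which channel feeds thresholding
  is a verification config (default: similarity). Exact score symmetry is
  obtained by canonicalizing the argument order on image bytes before
  matching.

The median-consensus model assumes a dominant global translation between
the two crops. In-plane rotation and the scale mismatch introduced by
bounding-box cropping make the true displacement a field, so only a band
around the median survives on jittered genuine pairs — similarity scores
well below 1 for genuine pairs are expected and harmless, because decisions
compare against imposter scores an order of magnitude lower.

## Verification protocol

The manifest (blacklisted rows excluded, unusable rows diverted to FTA) is
split 50/50 **by individual** — "no crossover" is only verifiable if no
animal contributes images to both halves; an image-level split exists
behind a flag for sensitivity analysis. Within each half, all
within-individual pairs form the genuine pool and imposter pairs are
sampled uniformly without replacement across individuals, at genuine
fraction *r* (realized fraction within 1/total of *r*). *r* is defined
over all pairs: r = 0.5 is a balanced 50:50 set.

Calibration takes the training scores and sets
`t* = max(imposter scores) + δ`, accepting iff `score ≥ t*`. δ is the
smallest positive gap between distinct observed scores (1 for
integer-valued scores such as raw key-point counts; configurable). This is
exactly the smallest threshold with zero false matches on the calibration
set, and the `+δ` construction makes the inclusive and exclusive readings
of "higher than the threshold" coincide on observed scores.

Rates follow the conventional orientation: FMR = imposter pairs accepted /
imposter pairs, FNMR = genuine pairs rejected / genuine pairs; the
identities TMR + FNMR = 100% and TNMR + FMR = 100% hold to machine
precision, and balanced accuracy equals (TMR + TNMR)/2. Rates over an
empty class are reported as undefined (`None`), never as 0. FTA is the
explicit ratio `100 · n_unusable / n_attempts`.

## Statistics

Per-category accuracy is a binomial proportion; its CI is the exact
Clopper–Pearson (beta-quantile) interval, with the closed-form boundaries
at x = 0 and x = n. Categories are compared with a Tukey-type studentized
range test on arcsine-stabilized proportions,
`q = √2·(φᵢ − φⱼ)/√(1/nᵢ + 1/nⱼ)` with `φ = 2·asin(√p)`, p-values from the
studentized-range distribution with k groups and infinite degrees of
freedom. This convention was chosen because it reproduces the published
significance pattern and lands within ~0.04 of one published q statistic
(3.71 vs 3.69); exact numerical agreement with the unstated original
variant is not claimed — agreement of the significance pattern is the
contract. Homogeneity letters are a compact letter display over maximal
cliques of the non-significant graph.

## Experiments

Four categories partition the evaluation by quality and angle: (1) high
0°, (2) high+medium 0°, (3) high 0°+45°, (4) high+medium 0°+45°; each is
calibrated and evaluated independently. The ratio sweep re-runs a category
at r ∈ {0.1, …, 0.5}, sharing a pair-score cache so each image pair is
matched once. The trivial baseline `100·(1−r)` quantifies the imbalance
bias the balanced operating point avoids. The harvest projection applies a
calibrated FMR to an annual harvest with half-away-from-zero rounding —
the shipped preset (35,001 animals at FMR 2.137%) is the best frontal
operating point; `run_full_study` instead projects the FMR its own best
category measured.

## Problem sizes and numerical choices

The shipped defaults run the full study on 80 individuals with at most 200
pairs per split, and the deepest test exercises a 120-individual
population — sizes chosen so a complete run stays desk-scale while keeping
≥10 genuine pairs per split in the sparsest category. Ties in the coarse
and fine argmax resolve to the first candidate in scan order; scores are
float64 once out of the matcher; tessellation, warping and matching are
deterministic for fixed seeds on a given platform (hypothesis tests run
derandomized). Degenerate inputs fail loudly: flat images score 0, empty
imposter sets refuse calibration, unusable captures reaching evaluation
raise instead of being silently scored.

## Known limitations

Synthetic-only validation (see the generator caveats above); a
translation-dominant consensus model that under-counts inliers under
rotation and scale change; no identification-mode (1:N) evaluation; no
DET/ROC beyond the single calibrated operating point; score distributions
with small imposter calibration sets make `max + δ` a noisy tail estimate,
visible as occasional test-set false matches at small population sizes.
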