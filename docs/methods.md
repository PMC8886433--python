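# Methods

## Registration model

Overlapping endoscope frames of near-planar tissue are related by a plane
projective transform (homography) `H`, a 3×3 matrix with `h33` fixed to 1,
i.e. 8 free parameters. The pipeline estimates `H` mapping image-2 pixel
coordinates into image-1 coordinates; the same convention is used by the
canvas/warping code and the synthetic generator, so estimated and true
transforms compare directly. Fixing `h33 = 1` is singular for transforms
with true `h33 ≈ 0`; those do not occur between overlapping frames of the
same surface and are out of scope.

Coordinates are 0-based pixels, `x` = column, `y` = row, y pointing down.
Gradient orientation is `θ = atan2(L(x,y+1) − L(x,y−1), L(x+1,y) − L(x−1,y))`
mapped to [0, 360): a rightward intensity ramp has θ = 0°, a downward ramp
θ = 90°. This fixes the quadrant handling that the bare gradient-magnitude/
direction formulas leave open.

## Detection

Gaussian scale space with base scale `sigma0 = 1.6` (the input is assumed
to carry 0.5 px of sensor blur, so the first layer is blurred by
`sqrt(1.6² − 0.5²)`), `intervals = 3` layers per scale doubling, and a
scale step `k = 2^(1/intervals)` so each octave spans exactly one doubling.
A literal `k = 2` is selectable (`k_literal_2`) for fidelity experiments;
it breaks the small-(k−1) approximation that justifies treating the DoG as
a scale-normalised Laplacian, which is why it is not the default. No
initial 2× upsampling; octave count defaults to `floor(log2(min(h,w))) − 3`.
Gaussian kernels are truncated at 4σ with reflected borders, which keeps
the constant-image invariant exact (DoG of a constant image is identically
zero).

Candidates are strict extrema over the 26-sample scale-space neighbourhood
(plateaus are never reported). Refinement solves
`x̂ = −(∂²D/∂x²)⁻¹ ∂D/∂x` with central differences at unit spacing,
re-centring on the neighbouring sample while any offset component exceeds
0.5, at most 5 times; candidates that wander out of the octave or hit a
singular quadratic are dropped. Acceptance requires refined contrast
`|D(x̂)| ≥ 0.03` — meaningful because input is normalised to [0, 1]
luminance (Rec. 601 for RGB) — and the spatial-Hessian curvature test
`Tr²/Det < (γ+1)²/γ` with γ = 10 (threshold 12.1; saddles with `Det ≤ 0`
always rejected). The trace/determinant form avoids computing eigenvalues;
the determinant uses `Dxx·Dyy − Dxy²`.

## Description

Orientation: a 36-bin histogram of gradient direction over a disc of radius
3·(1.5σ), each sample weighted by its gradient magnitude and a Gaussian of
width 1.5σ (the weight width is a choice; only the disc radius is pinned by
the method definition). Bins collect directions within half a bin width of
their centre. The global peak and every other local maximum strictly above
80% of it each emit an oriented keypoint; peak positions are refined by
3-point parabolic interpolation, ties broken toward the lower bin index.

Descriptor: a 4×4 grid of cells of side 3σ, rotated by −θ about the
keypoint, 8 direction bins of 45° per cell measured relative to θ —
16 × 8 = 128 components. Samples are distributed by trilinear interpolation
over (row cell, column cell, direction bin). The sampling window is
enlarged by √2 so the rotated grid stays covered (a corrupted printed
expansion factor in the source description was replaced by this geometric
requirement). Spatial weighting is a Gaussian of standard deviation equal
to half the window width; a variance-6σ Gaussian is selectable
(`gauss_variance_6sigma`) because the original description is ambiguous
between variance and standard deviation. The vector is L2-normalised,
clamped at 0.2 per component, and renormalised (the final renormalisation
is the standard convention; the clamp alone would leave a non-unit vector).
Gain invariance is exact (normalisation), offset invariance is exact
(gradients).

## Matching

2-NN Euclidean search. The KD-tree splits on the dimension of maximum
spread at the median; leaves hold up to 8 descriptors. Best-bin-first
search pops unexplored half-spaces from a priority queue keyed by axis
distance and stops when the queue empties, when every queued bin is
provably farther than the current second-nearest (making the unlimited-
budget search exact), or after 200 leaf visits. The budget replaces a
wall-clock cutoff in the original description: node counts are
reproducible, elapsed time is not. All ties break toward the lower
descriptor index, so results are deterministic and insertion-order
independent for distinct distances.

## Purification and verification

Stage 1: ratio screening `R = d1/d2 < 0.65` (strict) in both matching
directions, then the bidirectional cross-check `C = {(p,q) ∈ A : (q,p) ∈ B}`.
Candidates with `d2 = 0` (duplicate descriptors) cannot be scored and are
dropped with a warning.

Stage 2: RANSAC on C with 4-pair samples (any sample containing a
near-collinear triple — twice-triangle-area below 1e−6 of the squared
bounding-box diagonal — is resampled), exact DLT solve per sample, and the
inlier gate `d²ᵥ < t²` where `t² = χ²₂(1 − significance) · σ²`; at the
defaults (significance 0.01, σ = 1 px) `t² = 9.210`. The χ²-quantile
reading replaces a garbled integral bound in the printed derivation; the
squared 2-D transfer error of a Gaussian-localised point is σ²·χ² with 2
degrees of freedom, so the 0.99-confidence gate is the 0.99 quantile. The
required sample count `N = log(1−p)/log(1−(1−ε)⁴)` (p = 0.99) is re-derived
from the best consensus after every improvement (ε̂ = 1 − X/|C|; this
adaptive coupling is the standard completion of the MAX-update description,
which tracks the best count but does not say how it feeds back). The search
also stops after 200 consecutive non-improving iterations, operationalising
"the number of interior points no longer increases". The final model is a
least-squares refit on the maximal inlier set, with one refit/re-gate round
so the reported mask is consistent with the reported model. A single seeded
generator drives all sampling; default seed 0.

Verification: the image pair is accepted as a true match iff
`n_i > 8.0 + 0.3·n_f`. The binomial-model posterior behind that linear rule
is exposed for diagnostics with `p1 = 0.6`, `p0 = 0.1`,
`P(match) = 1e−6`, `P_min = 0.999`; `p1`/`p0` are not printed in the source
and affect only the diagnostic posterior, never the accept decision. Note
the rule needs `n_f ≥ 12` before acceptance is even possible (since
`n_i ≤ n_f`), so very sparse scenes are rejected by construction.

## Estimation and fusion

The DLT system stacks two rows per pair into a 2n×8 matrix and solves by
`lstsq`. Hartley normalisation (centroid to origin, mean distance √2) is
applied internally by default and undone on output: the raw normal-equation
path `(XᵀX)⁻¹Xᵀy` is numerically fragile at image-scale coordinates, but
remains available (`normalize=False`) and agrees to ~1e−6 on
well-conditioned data.

Fusion warps image 2 onto a canvas bounding both frames (backward mapping,
bilinear) and feathers the overlap: `d1` ramps linearly from 1 on image 1's
side to 0 on image 2's side (per row along the dominant displacement axis),
`d2 = 1 − d1`, so `d1 + d2 = 1` at every overlap pixel and output values
stay within the convex hull of the inputs. The printed blending formula
carries an extra factor ½ in the overlap term that contradicts the
partition-of-unity constraint printed beside it; the ½ is therefore omitted
by default and available as `literal_blend_halving` for fidelity tests. A
distance-transform weight (`blend_ramp_mode="distance"`) handles irregular
overlaps. Colour images are blended per channel; registration always runs
on luminance.

## Synthetic data

`generate_pair` renders a latent scene of multi-octave value noise
(5 octaves, persistence 0.85) passed through a sigmoid tone curve
(gain 8): plain band-limited noise is too flat to carry a realistic
keypoint density, whereas mucosal imagery is high-contrast. The two frames
sample the scene through the identity and through `H_true`; frame 2 then
receives multiplicative gain jitter (±5%), additive offset jitter (±2%)
and optional Gaussian sensor noise, and both frames are vignetted by a
circular field-of-view falloff (radius 0.95 of the half-diagonal,
smoothstep edge — the FOV circle of an endoscope still is clipped by the
sensor frame, so only corners darken). Default frame size is 180×240:
about a fifth of the area of a typical 500×412 endoscope still, carrying
proportionally fewer keypoints (tens rather than hundreds), which keeps
the full 20-seed end-to-end benchmarks to seconds. Pairs whose overlap
drops below 25% of frame 1 are refused as unstitchable by design.

What the generator does *not* emulate: specular highlights, radial lens
distortion, non-planar tissue parallax, motion blur, and colour. Passing
tests therefore demonstrate correctness of the geometry/matching machinery
under the stated image model, not robustness to every artefact of live
endoscopy.

`generate_matches` plants labelled correspondence sets: inliers are mapped
points with Gaussian localisation noise (σ = 1 px default); outliers are
60% independent uniform points and 40% near-miss mismatches (true location
plus a uniform annulus offset of 1.5–12 px). Purely uniform outliers are
essentially never admitted by the χ² gate, which would make RANSAC-only
precision saturate at 1.0; repetitive tissue texture in real imagery
produces near-miss mismatches, and the mixed model reproduces the
characteristic three-column precision ordering (raw < RANSAC-only < full
cascade). Ratio-test distances are synthesised from separated Beta
distributions (inliers Beta(4,5)·d2, outliers Beta(8,2)·d2) and mutuality
flags from Bernoulli(0.95)/Bernoulli(0.3), so the ratio and cross-check
stages run for real on planted sets.

## Numerical choices and degenerate inputs

- Tie-breaks: lowest index everywhere (search results, histogram peaks),
  for determinism.
- Duplicate keypoints after refinement are collapsed on rounded
  (octave, x, y, σ); when `max_keypoints` (default 600) is exceeded the
  strongest-contrast keypoints are kept.
- Flat orientation patches emit no keypoint; descriptor windows fully
  outside the image reject the keypoint; a zero-norm descriptor is
  rejected rather than normalised.
- `ransac_homography` raises below 4 pairs and flags failure (rather than
  raising) when no sample reaches 4 inliers.
- Images must be at least 16×16 for detection; requesting more octaves
  than the image supports raises an error naming the feasible maximum.

## Known limitations

- Pairwise registration only: no global bundle adjustment, so chaining
  many frames accumulates drift.
- The h33 = 1 parameterisation excludes transforms with vanishing h33.
- Best-bin-first accuracy below the exact-search budget is probabilistic;
  the 200-leaf budget recovers the true nearest neighbour for ≳90% of
  queries on random 128-d data (measured, not guaranteed).
- The verification rule cannot accept pairs with fewer than 12 consistent
  matches regardless of their quality.
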