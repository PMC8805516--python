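# Methods

This note documents the models, parameters and design choices behind
`aneuscan`, and what the synthetic-phantom experiments do and do not
demonstrate.

## Synthetic phantoms

The phantom generator stands in for clinical TOF-MRA, which shows bright
arteries over darker tissue. Each case is a deterministic function of
`(PhantomConfig, seed)`; independent random substreams drive vessel
geometry, background noise and aneurysm placement, so regenerating with
`noise_sigma=0` yields the identical noiseless signal component (also kept
in `volume.meta["signal"]`).

- **Vessels.** Centerlines are correlated random walks (reflecting off the
  volume faces so tubes keep their length in the field of view)
  interpolated by cubic splines; every vessel after the first branches off
  an earlier one, so any phantom with ≥ 2 vessels contains a bifurcation —
  deliberately reproducing the dominant false-positive source of blob
  detectors on angiograms. Intensity follows a Gaussian cross-section
  `I·exp(−d²/2r²)`; the vessel mask is the tube interior `d ≤ r`.
- **Aneurysms.** Spheres of intensity equal to the vessel intensity,
  centered one nominal vessel radius (the midpoint of the configured
  radius range) outward from a random wall voxel along the local outward
  normal — a hemispheric protrusion, the simplest shape matching the blob
  filter's target. Equivalent diameters are drawn uniformly from the
  configured range; diameters above 15 mm are rejected by construction
  (clinically such aneurysms are not a detection-software problem).
  Ground-truth masks are the rasterized spheres; the stored equivalent
  diameter is recomputed from the mask, `(6V/π)^{1/3}·spacing`, and agrees
  with the sampled diameter to within one voxel.
- **Defaults.** 0.3906 mm isotropic spacing (so voxel↔mm arithmetic
  matches the resampled clinical grid), vessel intensity 100, background
  20, noise σ 5 — a bright-artery regime of ~16 noise sigmas of contrast,
  chosen as a clean screening-quality acquisition. No intensity statistics
  were available to calibrate against, so the SNR is a free parameter.
- **Location labels** use a synthetic vocabulary (`trunk`, `bifurcation`,
  `distal`) assigned by distance to recorded branch points and centerline
  endpoints; arterial territories (ICA, MCA, …) are not simulated.
- Cohorts are written as uncompressed `.nii` (gzip embeds a timestamp,
  which would break byte-level reproducibility of checksums) plus a JSON
  manifest with per-case seeds and the aneurysm table.

**What the phantoms do not emulate:** MR flow physics and flow-related
signal loss, skull/soft-tissue background, anatomy, scanner-dependent
noise spectra, and irregular or fusiform aneurysm shapes. Passing tests on
phantoms validates the machinery (filters, labeling, training, voting,
scoring) and directional behavior, not clinical performance.

## Preprocessing

- **Resampling** to 0.3906 mm isotropic, trilinear, with world position
  `index·spacing` (axis-aligned; no oblique affines). Output shape is
  `round(shape·spacing/target)` per axis, preserving world extent to one
  voxel. Masks would use nearest-neighbor.
- **Intensity standardization** uses histogram landmarks: deciles
  {10,…,90} as landmarks, clip bounds (p1, p99) anchored affinely to a
  [0, 100] standard range, standard values = across-volume means of the
  anchored landmarks, and a piecewise-linear map at application time with
  clamping outside the clip bounds. The map is monotone, fixes the
  landmarks, and is idempotent on the standard scale. A constant volume
  (degenerate histogram) is rejected.
- **Artery extraction** thresholds at mean + 3·std computed over voxels
  with intensity > 0 (excludes resampling padding; on MR magnitude-like
  all-positive data this is simply the full volume). On pure Gaussian
  noise the mask is the upper ~0.135% tail, a property the tests measure.
  A constant volume has σ = 0; keeping everything would flood candidate
  extraction, so the degenerate case returns an empty mask with a warning.
- The standardization scale is trained on the training-side volumes of the
  current experiment only (one scale per experiment, not per scanner).

## Candidate extraction

The selective enhancement filter computes Gaussian-derivative Hessians at
each scale, orders eigenvalues by magnitude |λ₁| ≥ |λ₂| ≥ |λ₃|, and forms
blob/line/plane responses (formulas in the README) with γ = 2 scale
normalization (σ² in voxel units); per-voxel maxima over scales give the
final responses and the blob argmax scale. Division is guarded by
ε = 10⁻¹²; the volume is mean-centered first so that float32 roundoff in
the derivative filters stays relative to the signal (a constant volume
yields exactly zero everywhere). For an isotropic Gaussian spot of size σ₀
the center blob response is `A σ² σ₀³/(σ₀²+σ²)^{5/2}`, maximized at
σ = σ₀√(2/3) with value `A·(2/3)(3/5)^{5/2} ≈ 0.186·A`; the tests require
5% agreement. Default scale set: σ ∈ {0.6, 1.0, 1.6, 2.4, 3.6} mm,
covering 3–15 mm bulges. When a mask is supplied, eigen-decomposition is
restricted to it (smoothing always sees the whole volume, so in-mask
responses are unchanged); arteries are a few percent of a volume, which
makes this the main speed lever.

Candidate points are blob-response local maxima inside the artery mask
above a response floor (default: the in-mask 95th percentile), with greedy
non-maximum suppression (default radius 3 mm) and a deterministic
response-then-coordinate ordering. Patches (default side 32 voxels
= 12.5 mm; any ≤ 12 mm aneurysm fits, 48 would contain 15 mm) are cropped
with zero padding at edges. Labels: *positive* iff some annotation mask —
equivalently its tight bounding box — lies entirely within the patch
bounds; *partial* iff an annotation intersects the bounds but none is
contained (excluded from classifier training); else *negative*.

Pre-filter features: sphericity `π^{1/3}(6V)^{2/3}/A` of the bright
connected component at the patch center (surface area from marching cubes
on the mask smoothed with σ = 0.5 voxel — meshing the raw binary mask
overestimates curved areas by the staircase factor; with this smoothing a
digital sphere scores ≈ 0.97 and an elongated tube ≈ 0.7), component
volume and equivalent diameter, max/mean of each shape response in the
patch, blob/line and blob/plane ratios at the peak, center-to-boundary
distance, and intensity mean/std. Empty components get sentinel zeros.
The pre-filter itself is a gradient-boosted tree classifier behind a
pluggable fit/score contract; its operating threshold is the score
quantile retaining ≥ 99% of positives on the calibration set (capped at
0.5). It can be applied at training time only or also at inference
(config switch).

## Multi-view MIP panels

The 15-view set is: axial/coronal/sagittal (proper 90° rotations bringing
each axis into projection position) plus rotations of ±30° and ±45° about
each of X, Y, Z — the natural enumeration yielding exactly 15; it lives in
one function (`orientation_set`) so an alternative convention is a
one-line change. Projection is always along the first array axis after
rotating the patch about its center (trilinear). Out-of-patch samples take
the patch minimum rather than zero so that every tile pixel stays inside
the patch's intensity range (identical to zero padding for
background-zero standardized patches). Tiles are concatenated vertically
without per-tile rescaling, preserving relative brightness across views.

## Classifiers

The three architectures share one branch design: a stride-2 convolution
stem, then `branch_depth` squeeze-and-excitation residual stages (stage i:
conv–ReLU–conv with SE channel gating and a projected shortcut, stride 2,
`base_channels·2^i` channels), ending in global average pooling. The 2D
branch consumes the (15·S × S) panel, the 3D branch the raw S³ patch; a
stand-alone model adds a one-logit dense head, and the MD model
concatenates both branches' pooled features into one fresh head — its
parameter count is exactly branch(2D) + branch(3D) + head. Both MD
branches train simultaneously from scratch; no weight sharing or
pre-training.

Layers, gradients and the Adam optimizer are implemented directly on
numpy arrays; convolutions are single-GEMM im2col in float32, and
correctness is pinned by tests against a float64 offset-loop reference.
All randomness (init, shuffling, dropout) flows from `NetConfig.seed`, so
training and prediction are bit-reproducible.

Defaults (hyperparameters are deliberately configurable; 4-fold
case-level cross-validation is the sanctioned tuner): 3 stages, base 16
channels, SE reduction 16, binary cross-entropy with positives weighted
by inverse prevalence (switchable), Adam at 10⁻³, batch 32, dropout 0,
optional flip/rotation augmentation off by default, inputs divided by 100
(the standard intensity range) to be O(1). Training holds out 20% of
cases for validation, records per-epoch train/validation loss, and
returns the best-validation checkpoint.

## Aggregation and FROC

"The part of the artery determined positive" is formalized as a
26-connected component of the union of positive candidates' footprints
(patch bounds ∩ artery mask). The decision threshold is strict (p > 0.5
by default; p = 0.5 is negative), and "more than five candidate voxels"
reads as vote count ≥ 6. Regions closer than 16 voxels (≈ 6.25 mm at
0.3906 mm) merge, keeping the higher score and its representative point
(footprint centroid rounded to a voxel); two sub-threshold true-positive
regions on one aneurysm therefore merge rather than double-count.
Scanning in descending score with a coordinate tiebreak makes both steps
independent of candidate input order.

One subtlety the property tests surfaced: the *number* of emitted
detections is not monotone in the threshold τ — removing a low-probability
connecting candidate can split one component into two, each still passing
the vote minimum. The monotone invariant is the emitted *footprint*
(voxel territory), which can only shrink as τ rises; that is what the
tests assert.

FROC sweeps the region score (maximum member probability) with the vote
rule applied at the fixed τ = 0.5 candidate level; sweeping τ itself is
supported via config. A detection is TP iff its footprint shares ≥ 1 voxel
with an aneurysm mask; an aneurysm counts once regardless of how many
detections hit it; sensitivity is pooled over aneurysms (not averaged over
cases) and FPs are averaged over cases. Operating points interpolate
linearly between adjacent curve points; unreachable targets are reported
explicitly. Size bins: < 3.0, 3.0–5.9, 6.0–8.9, ≥ 9.0 mm.

## The scaled phantom study

`pipeline.small_study_config` defines the standing end-to-end experiment:
50 cases (40 train / 10 test at the 80/20 case-level split; the training
side donates 20% of its cases to validation inside `train`), 64³ voxels at
0.3906 mm (25 mm field of view), three vessels of radius 0.6–1.2 mm and
two 3–6 mm aneurysms per case, patch side 24 (9.4 mm), scale set
{0.8, 1.2, 1.8, 2.7} mm, response floor at the in-mask 30th percentile
with 0.8 mm suppression radius and ≤ 60 candidates/case, and a small
network (2 stages, base 8, SE reduction 8, 10 epochs at 2·10⁻³). These
sizes were chosen so the whole study runs in minutes on one CPU core;
candidate counts are ~20–30 per case.

Two deliberate departures from the clinical-scale defaults:

- **Vote minimum 2 instead of 6.** Candidate points here are sparse local
  maxima; a phantom aneurysm attracts a handful of candidates, not the
  dense candidate fields of full-size clinical volumes that make "more
  than five" meaningful. The library default stays 6.
- **Pre-filter disabled.** On clean phantoms the hand-crafted features
  separate positives from negatives almost perfectly, so applying the
  pre-filter before training strips the negative class and leaves the
  CNNs nothing to contrast. It keeps its own dedicated tests.

On this study every architecture's validation loss beats the
constant-probability baseline, and the MD model's FPs/case at the
sensitivity all three architectures reach is no worse than the worse of
the single-branch models (asserted by majority over seeds 1–3). The
curves saturate near-perfect detection — the phantoms are easy by
clinical standards — so the study demonstrates correct plumbing and the
directional fusion behavior, not clinical difficulty. External-test
emulation (train on one cohort, test on another generated with different
SNR/geometry) is expressible through `ExperimentConfig` but is not part
of the standing study.

## Known limitations

- The numpy network library targets small models; there is no GPU path,
  batch normalization, or learning-rate scheduling.
- The phantom intensity model is piecewise-deterministic signal plus
  i.i.d. Gaussian noise; no Rician magnitude statistics.
- Aggregation stores detection footprints as dense boolean volumes,
  appropriate for the ≤ 128³ volumes used here.
- The 15-view enumeration is a convention choice; only its cardinality
  and the three canonical leading views are contractual.
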