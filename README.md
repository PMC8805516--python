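# aneuscan

Candidate-based detection of cerebral aneurysms on time-of-flight MR
angiography (TOF-MRA)-like volumes, built around a multidimensional
classifier that fuses planar and stereoscopic views of each candidate.

Unruptured cerebral aneurysms are screened for with TOF-MRA, where arteries
appear bright without contrast. Automated detectors reach high sensitivity
but flood the reader with false positives, most of them at vessel
bifurcations and sharp curvature. `aneuscan` implements the full
candidate-based pipeline for studying this trade-off — including a fused
2D+3D ("multidimensional", MD) classifier whose purpose is to cut false
positives while keeping sensitivity — together with a seeded synthetic
vascular phantom generator, so every stage runs and is tested end to end
without patient data.

## Pipeline

1. **Preprocessing** (`aneuscan.preprocess`) — resampling to an isotropic
   0.3906 mm grid; histogram-landmark (Nyúl–Udupa) intensity
   standardization mapping each volume's decile percentiles onto a learned
   standard scale; artery extraction by thresholding at μ + 3σ of the
   standardized intensities.
2. **Candidate extraction** (`aneuscan.enhance`) — a multiscale Hessian
   *selective enhancement filter*. With eigenvalues ordered
   |λ₁| ≥ |λ₂| ≥ |λ₃| and scale σ (in voxels):

   - blob: σ²·λ₃²/|λ₁|  (λ₁,λ₂,λ₃ < 0)
   - line: σ²·|λ₂|(|λ₂|−|λ₃|)/|λ₁|  (λ₁,λ₂ < 0)
   - plane: σ²·(|λ₁|−|λ₂|)  (λ₁ < 0)

   maximized per voxel over scales. Blob-response maxima inside the artery
   mask become candidates; cubic patches are cropped around them and
   labeled positive (patch contains an entire aneurysm), partial
   (discarded from training), or negative. A gradient-boosted pre-filter
   over hand-crafted features (sphericity, shape-response statistics, …)
   can drop obvious negatives at ≥ 99% positive retention.
3. **Multi-view projection** (`aneuscan.mipgen`) — each patch is viewed
   from 15 orientations (3 canonical axes plus ±30° and ±45° rotations
   about X, Y, Z), maximum-intensity-projected, and the 15 tiles stacked
   vertically into one (15·S × S) panel.
4. **Classifiers** (`aneuscan.nets`) — three squeeze-and-excitation
   residual networks trained from scratch: **2D** (the MIP panel), **3D**
   (the raw S³ patch), and **MD**, which pools both branches with global
   average pooling, concatenates the feature vectors and outputs a single
   aneurysm probability through a fully connected head.
5. **Aggregation** (`aneuscan.aggregate`) — candidates with probability
   > 0.5 vote; a 26-connected region of their footprints is a detection
   only when more than five candidates support it (configurable);
   detections closer than 16 voxels (≈ 6.25 mm) merge.
6. **Evaluation** (`aneuscan.froc`) — free-response ROC: pooled
   sensitivity versus false positives per case across score thresholds,
   operating points (FPs/case at 80% sensitivity, sensitivity at
   3 FPs/case), and size/location breakdowns.

The phantom module (`aneuscan.phantom`) generates the study data: spline
centerline vessels with bifurcations, Gaussian cross-sections and
background noise, plus spherical bright bulges (3–15 mm equivalent
diameter) implanted on vessel walls with voxel-accurate ground truth.

## Worked example

Run the scaled phantom study (12 cases: 9 train / 1 validation-by-split /
2 test, two 3–6 mm aneurysms each) for all three architectures:

```bash
aneuscan run --seed 7 --n-cases 12 --archs 2d,3d,md --out demo_run
```

prints

```
2d: max sensitivity 1.000 at 0.00 FPs/case; sensitivity at 3 FPs/case: 1.000
3d: max sensitivity 1.000 at 0.00 FPs/case; sensitivity at 3 FPs/case: 1.000
md: max sensitivity 1.000 at 0.00 FPs/case; sensitivity at 3 FPs/case: 1.000
results bundle in demo_run
```

and writes per-architecture FROC curves (`froc_md.csv` below), detection
records, stratified size/location tables and an `experiment.json` manifest:

```
threshold,fps_per_case,sensitivity
0.6078669393160224,0.0,0.5
0.5982894282651932,0.0,1.0
```

Each FROC row is one score threshold: at the top threshold only the
highest-scoring detection survives (half the test aneurysms found, no
false positives); lowering it to ~0.598 finds all of them, still without
false positives. On these clean phantoms the task saturates quickly —
`docs/methods.md` discusses exactly what that does and does not show.

Library use mirrors the CLI:

```python
from aneuscan.pipeline import small_study_config, run_experiment
results = run_experiment(small_study_config(seed=1))
print(results["archs"]["md"]["operating_points"])
```

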