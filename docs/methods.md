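# Methods

This note records the models, conventions and numerical choices behind
`toromorph`, in the order data flows through the pipeline.

## Imaging model and preprocessing

Input frames are single-channel rasters with a physical calibration in
nm/px.  The calibration is a required parameter: dielectric micrographs do
not embed it, and every length this package reports scales with it.  The
synthetic default is 10 nm/px, chosen so a 590 nm particle spans ~59 px and
fits the 100 px crop geometry of the detection stage.

Preprocessing follows the two-Gaussian scheme: sharpen with an 11 px / 1.2σ
kernel, then subtract a 400 px / 200σ Gaussian of the sharpened image as
the background estimate.  The subtraction order is chosen so dark
(low-dielectric) particles stay dark; an `invert` flag covers the opposite
convention.  Both filters use reflective edge handling, which avoids the
border dimming that zero padding would cause in later window
classification.  The operator is linear and, for frames much larger than
the background kernel, leaves a near-zero-mean high-pass image.

## 3-D particle models

The melanoma-line particle is a torus whose three printed dimensions
(outer diameter 590 nm, central hole 330 nm, axial thickness 170 nm) are
mutually inconsistent with a circular tube cross-section (radial width
(590−330)/2 = 130 nm ≠ 170 nm).  The tube is therefore elliptical:
centreline radius R = (590+330)/4 = 230 nm, radial semi-axis a = 65 nm,
axial semi-axis b = 85 nm, which reproduces all three printed numbers
exactly.  The melanocyte particle is a prolate spheroid, 710 × 280 nm.
Grids are 181³ (toroid) and 100³ (ellipsoid) voxels; the physical pitch is
not printed anywhere, so it is set to 4 and 8 nm respectively, the largest
values for which the printed grids enclose the models with margin.

Projections rotate the *ray directions*, not the voxel grid, so the model
is sampled once (nearest voxel) along each ray at half-voxel steps; at 0°
and 90° the sampling lattice coincides with the voxel lattice and the
silhouette is exact.  Whether real image contrast is linear in path length
is unknown; the projection reports path length and leaves the mapping to
the renderer (below).

## Synthetic scenes

Scenes emulate the transmission contrast of the real data: a bright
background (mean 100, Gaussian noise σ = 2) with a few smooth nuisance
blobs, and dark particles with peak darkness 30 (≈15:1 contrast-to-noise).
Particle darkness follows `(thickness / max)^0.5`: dielectric contrast
saturates with material thickness, and the square root gives the crisp
particle rims seen in real dielectric images, where a linear mass-thickness
mapping would fade the rim into the noise.  The exponent is configurable
(`contrast_gamma`; 1 = linear).

Ellipsoidal particles are rendered with the closed-form chord length of a
triaxial ellipsoid viewed along a short axis, so their silhouette is
*exactly* the drawn major × minor ellipse at a random in-plane angle, and
the recorded ground-truth axes are exact by construction.  Toroids are
voxelised and ray-projected at a drawn tilt; a tilted torus outline has no
simple closed form, so their ground-truth axes are measured on the rendered
mask (the mask itself is the ground truth; the generator-level invariant
that mask axes match recorded axes within 1 px is tested).  Default axis
distributions centre the major axis on the observed 590 ± 23 nm particle
diameter.  Particles are placed with non-overlapping bounding boxes
(rejection sampling with a bounded budget); overlap-free scenes keep
recall and centre-error statistics well defined.  All randomness flows
from one integer seed through one `numpy` Generator.

What the generator does **not** emulate: particle clustering and partial
occlusion, nucleus texture, detector shot-noise statistics (not
characterised for this modality), stage-dependent internal ultrastructure.
Tests passing on these scenes therefore demonstrate the correctness and
calibration of the *pipeline*, not performance on real micrographs.

## Window classifiers

Both CNNs take 50×50 single-channel windows (100×100 at full resolution,
reduced by 2×2 block averaging).  Architectures:

* detector: conv 21@7×7 → 16@5×5 → 16@3×3 → 32@3×3, BN + ReLU after each,
  2×2 max-pool after the first three (50→44→22→18→9→7→3→1);
* masker: conv 35@11×11 → 21@7×7 → 16@3×3 → 32@3×3.  With valid
  convolutions these filter sizes admit only two poolings on a 50 px input
  (50→40→20→14→7→5→3), so pooling follows the first two layers only.

Both heads are fully connected 128–64–2 with ReLU, ending in softmax.
Training is shuffled mini-batch SGD (batch 128, lr 0.01, momentum 0.9); the
detector needs no schedule (it separates in 1–2 epochs), while the masker's
boundary discrimination benefits from a ×0.1 learning-rate step late in
training (default at epoch 8 of the scaled 12-epoch runs).  Batch
normalisation uses conv→BN→ReLU ordering, ε = 1e-5, momentum 0.1, and in
evaluation folds to a per-channel affine.  Labels are {0,1} internally and
{1,2} (background/particle) at every interface and file format.

**Intensity normalisation is per source frame**, not per window: the whole
scene (or the whole 200×200 masking context) is standardised to zero mean
and unit variance once, and every window inherits that affine.  This
matches how a whole observation image is normalised before scanning, and it
is what makes shared-computation scanning possible — per-window affines
would break the equality between dense and per-window evaluation after the
first nonlinearity.

## Bit-exact sliding evaluation

The stride-1 raster scan is computed densely ("à trous"): convolutions run
once over the whole frame, and each 2×2 pooling branches the feature maps
into the four phase offsets, so every window's features are sub-windows of
some phase map.  Two implementation details make the dense path agree
*bit-for-bit* with classifying each window alone: (i) evaluation-mode BN is
the same folded affine in both paths; (ii) every inference matmul runs
through a fixed 512-row-block GEMM (`nn.mm_eval`), because BLAS selects
different kernels — and different summation orders — for different row
counts, which otherwise perturbs identical dot products in the last ulp.
Training uses plain GEMMs (no equality requirement).  The equivalence is
asserted by tests against explicit per-window loops.

## Detection and masking inference

The response map value is 1 + P(particle) ∈ [1, 2].  The map is smoothed
(25 px / 7σ) and the 80 % rule is applied *per response peak*: every local
maximum whose absolute response reaches the 1.2 floor defines a region at
80 % of its own peak height, and each region yields one detection.  The
floor keeps particle-free scenes detection-free; the per-peak reference
matters because smoothing spreads a particle's response in proportion to
its size — thresholding at 80 % of the *scene-wide* maximum instead would
couple the cutoff to the largest particle present and systematically drop
small ones (measured as a +16 nm bias in recovered cohort means before the
change, with missed particles averaging 100 nm smaller than detected ones).
Scene-global min–max and absolute-cutoff readings remain available as
options.  Each region's centre is its response-weighted centroid: the
smoothed peak is a near-flat plateau, where a raw argmax is biased toward
its first raster element while the centroid recovers true centres to ~1 px.
Map borders where the window does not fit are absent from the map rather
than padded and classified.

Masking classifies the half-resolution pixel grid of a 200×200 context by
default and upsamples ×2 (nearest), matching the training geometry at a
quarter of the cost; `full_res=True` classifies all four reduction phases
and is the pipeline default, since axis estimates benefit from the finer
boundary.  Border pixels whose window does not fit are background.

The binary mask thresholds the probability map at the 0.5 class boundary,
but where that boundary falls relative to the true silhouette edge drifts
by a fraction of a pixel with the training draw, which moves axis estimates
by a few nm per run.  The pipeline therefore calibrates the threshold after
training: it predicts masks for the training contexts and picks the
threshold at which total predicted area equals total true mask area
(`calibrate_mask_threshold`).  The calibration uses only the training
masks — which the workflow has by construction, since they are the
supervision — never evaluation data.

## Morphometry conventions

* Largest 8-connected component, holes filled before measurement, so an
  annular (toroidal) silhouette reports its outer diameter — and its hole
  is measured separately (fill-holes minus mask, equivalent-ellipse major
  axis of the largest hole).
* Axes: second-central-moment equivalent ellipse (the convention of the
  standard region-analysis toolchains).  Feret extents (max/min caliper
  width over pixel centres, plus one pixel) are reported alongside because
  for non-convex silhouettes the physical thickness is a caliper width:
  the moment minor axis of an edge-on torus is ~1.15× its thickness.
* Circularity: 4πA/P² with the 4-direction Crofton perimeter, which is
  unbiased on digitised convex shapes (the weighted boundary walk
  overestimates a disk's perimeter by ~3 %); values are clipped at 1.
  Circularity of elongated shapes is estimator-dependent at the few-percent
  level; comparisons should use one convention throughout.
* Correlation: Pearson product–moment between circularity and major axis;
  undefined inputs (constant fields, n < 3) raise rather than returning 0.

## Pipeline and the parameter-recovery study

`run_pipeline` chains simulate → preprocess → train → detect → mask →
measure → summarise under one config and seed; identical config + seed
reproduces reports and CSVs bit-for-bit.  Detections without a ground-truth
match within 25 px are excluded from measurement — the automated analogue
of the manual screening of mask quality in the original workflow (merged
neighbours are the main source).

The recovery study simulates twelve 900×900 scenes (25 particles each,
≥ 300 total) of face-on ellipsoids whose silhouette axes are drawn from the
day-2 melanoma-line distributions (major 519 ± 90 nm, minor 329 ± 72 nm;
pairs drawn with minor > major swapped, a correction whose analytic effect
on the means is ~2 nm).  Networks are trained on crops and masks from the
same scenes — as in the original workflow, where training images come from
the analysed dataset — then every matched detection is masked at full
resolution and measured.  Scaled problem sizes used throughout the package:
detector 90 base crops ×36 rotations, 4 epochs; masker 24–48 sources ×
125–150 samples, 12 epochs.  These sizes are the package's study
conditions; the paper-scale counts (546 crops ×36 = 19 656; 190 sources ×
1000 = 190 000) are exercised as arithmetic, not trained.

## Known limitations

* The masker's decision boundary sits within ~½ px of the true silhouette
  edge on clean synthetic data; residual axis bias after the full chain is
  a few nm at 10 nm/px and is covered by the two-standard-error recovery
  check, but on noisier real data the bias would need re-validation against
  hand masks.
* Touching or overlapping particles are not separated; the generator
  avoids them and real crowded fields would need an instance-separation
  step.
* The Raman module assumes grid-aligned, symmetric peaks and a flat
  baseline; no fluorescence-background or cosmic-ray handling.
* Determinism is guaranteed within a fixed BLAS/thread configuration;
  training histories are reproducible run-to-run on the same machine.
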