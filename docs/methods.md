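# Methods

This note documents the models and procedures implemented in `vesselkit`,
their assumptions, the parameters that matter, and the numerical choices
made where the design was genuinely open. No empirical claim here goes
beyond what the test suite and `scripts/acceptance.py` themselves compute.

## Conventions

All volumes are `(z, y, x)` with z the imaging-depth axis; voxel spacing is
`(dz, dy, dx)` in micrometres. Masks are `uint8` {0, 1}. Displacement
fields are pull-back fields in pixel units: `out(y, x) = in(y + u_y,
x + u_x)`. Foreground connectivity is 26 throughout; background (hole
definition) uses the dual 6-connectivity.

## Motion correction

In-vivo MPM acquires one slice at a time, so respiration and heartbeat
displace slices laterally and nonuniformly. Correction chains 2D
diffeomorphic demons registrations: slice z is registered to the
*already-corrected* slice z−1, with slice 0 the fixed reference. The
demons cost is mean squared intensity error; update and displacement
fields are Gaussian-smoothed with σ = 1.3 px (the default exposed as
`smoothing_sigma`), and invertibility comes from composing small
diffeomorphic steps (SimpleITK's `DiffeomorphicDemonsRegistrationFilter`).
Iteration count (50) and the 3-level shrink pyramid are not prescribed by
the method itself; they are config-exposed defaults that converge on the
phantoms used here.

Registration quality is assessed as the relative reduction of
adjacent-slice MSE. That measure is only meaningful when motion, not
anatomy, dominates slice-to-slice differences — on oblique vessels a
moving cross-section contributes anatomical MSE that registration should
*not* remove. The recovery fixture (`penetrating_vessel_phantom`)
therefore uses vessels diving along z, as penetrating cortical vessels do;
there the injected jitter dominates and demons removes >90% of it.

## Intensity normalization and resampling

The 1st and 99th intensity percentiles of the whole volume map linearly to
0 and 1; the extreme 1% of voxels clip. Percentiles over the full volume
(rather than per slice) are the default; normalization is monotone, so
voxel ordering is preserved up to clipping. Volumes are trilinearly
resampled to isotropic 1 µm³ voxels (`round(shape·spacing/target)` output
grid, edge-clamped); masks use nearest-neighbor to stay binary.

## The patch CNN

Fixed geometry: input 33×33×7 (x, y, z), output 5×5×1×2. All convolutions
are unpadded; this is what makes the geometry close: 33 → 31 → 29 → 27
after three 3×3×3 convolutions (32 channels; depth 7 → 5 → 3 → 1), a 2×2
in-plane max-pool with ceil semantics (27 → 14), two 3×3 convolutions
(64 channels; 14 → 12 → 10), a second pool (10 → 5), then dense 1024
(ReLU, 50% dropout) and a dense layer reshaped to 5×5×1×2 logits with a
softmax over the two channels. Pooling is 2D because the depth extent is
already 1 after the third convolution. Parameter count: 1,802,354.

The loss is cross-entropy restricted to non-true-negative voxels: a voxel
with label 0 and foreground probability below 0.5 contributes nothing.
Class membership is non-differentiable gating (the mask is recomputed each
step from the current probabilities; gradients flow only through the
cross-entropy of masked voxels). Probabilities are clipped at 1e-7 inside
logarithms. The per-step loss is normalized by the number of contributing
voxels, which stabilizes Adam's effective step across the severe and
varying class imbalance.

Implementation is pure NumPy (float32 BLAS matmuls). Convolutions are
computed as one matrix product per in-plane kernel offset over a strided
window view whose contraction axis spans the contiguous `(kx, c)` block;
gradients reuse the same kernels (input gradients via a transposed-kernel
convolution of the zero-padded output gradient). Strides for these views
are derived from array shapes, never read off the arrays — NumPy reports
arbitrary strides on size-1 axes even for contiguous arrays. Minibatches
are processed in micro-chunks of 8 patches (summed, then normalized
jointly — bitwise the same objective as one large batch) because small
chunks keep the convolution activations cache-resident. Fixed seeds give
bit-reproducible training.

Presets: `exploration` (lr 1e-4, 100 epochs, minibatch 1000) and
`finetune` (lr 1e-6, 30,000 epochs, minibatch 1000) match the published
training schedules; `desk` (lr 1e-3, ≤200 epochs, minibatch 256) is the
CPU-scale configuration used by the tests, with early stopping when
validation Jaccard improves by less than 0.01 for two consecutive epochs.
On the 64³ phantom this converges in roughly 10 epochs. Training sampling
is stratified: by default half the tiles have at least one foreground voxel
in their 5×5×1 target (the sampling policy is not part of the published
method; the loss already handles imbalance).

Inference tiles the volume so 5×5×1 output blocks partition it exactly
(stride 5, 5, 1); context beyond the borders comes from reflection
padding, and every voxel receives exactly one probability. Test-time
uncertainty runs n stochastic passes with dropout active, averages the
foreground probabilities and reports the binary Shannon entropy
(H(0)=H(1)=0, H(0.5)=1 bit).

## Post-processing

Fill holes (background pockets not 6-connected to the exterior), 3×3×3
boxcar mean re-binarized at 0.5 (computed as an exact integer neighborhood
sum ≥ 14; reflective borders), then delete 26-connected components smaller
than 100 voxels (strictly fewer). `fill_holes` and `remove_small_objects`
are idempotent; the mean filter is a discrete curvature flow and may shave
a few voxels off highly curved caps on repeated application — the chain is
only *nearly* idempotent, which the tests assert explicitly.

## Centerline graphs

Thinning uses the Lee–Kashyap–Chu algorithm (scikit-image). A practical
limitation worth knowing: that implementation can erase symmetric solids
of even diameter entirely, so the bundled phantoms center tube axes on
integer voxel coordinates.

Connectivity repair bridges breaks left by RBC shadows: dilate the
skeleton with a Euclidean ball of radius 5 (spacing-aware,
center-within-radius voxelization), mean-filter, fill 2D holes per
z-slice, re-thin, then mask with the segmentation dilated by radius 1.
The final mask bounds how large a gap can be healed: surface gaps up to
about twice the mask dilation radius.

Graph extraction classifies skeleton voxels by 26-neighbor count
(1 → endpoint, ≥3 → junction, 2 → path interior). Adjacent junction
voxels merge into one node (representative: the member nearest the
cluster centroid) — in 26-connectivity a T-junction inevitably inflates
into a small cluster because main-line voxels gain diagonal neighbors.
Edges are maximal interior chains; self-loops, multi-edges and isolated
cycles (anchored at a node of kind `"loop"`) are preserved.

Pruning iterates four rules to a fixed point (each pass strictly removes
voxels, so termination is guaranteed), re-deriving node kinds each pass so
junctions that lose their branches melt back into vessel interiors:

1. *Short dead ends*: an edge with exactly one degree-1 endpoint is
   removed when deleting it would remove fewer than 11 voxels. The
   deletable set excludes voxels used by other edges and keeps enough of
   the junction cluster to preserve its connectivity; this makes the count
   agree with the intuitive "branch length" despite cluster inflation
   (10-voxel branch removed, 11-voxel branch kept). For branches attached
   diagonally rather than perpendicularly the count can differ by one
   voxel; the tie-break is "voxels actually deleted".
2. *Single voxels at junctions*: cluster voxels absorbed by diagonal
   adjacency are removed one per cluster per pass, but only if the cluster
   stays connected and no internal shortest Euclidean path between edge
   attachment voxels grows — this protects the true junction core.
3. *Isolated voxels* are removed. (Free-floating multi-voxel segments are
   whole vessels and are kept.)
4. *Self-loops of one or two interior voxels* are removed.

## Morphometry

Length is the stepwise Euclidean arc length of the path in µm. Tortuosity
is length over end-to-end distance (exactly 1 for straight paths; NaN for
closed loops, excluded from distributions). Diameter is estimated at each
centerline voxel as twice `EDT − 0.5·voxel`, averaged along the path: the
Euclidean distance transform measures to the nearest *background voxel
center*, and the half-voxel correction places the wall halfway between the
last foreground and first background centers. On digital cylinders of
radius 2–5 µm this recovers diameters with mean absolute error well under
1 µm, and a 1-voxel-wide line reads ≈ 1 voxel. The estimator is validated
by phantom recovery, not by matching any published table. When centerline
repair routes a few voxels just outside the mask (it constrains them only
to the 1-voxel-dilated segmentation), `measure_segments` averages the
diameter over in-mask voxels.

Capillaries are segments with mean diameter strictly below 10 µm.
Distributions are reported as relative-frequency histograms and empirical
CDFs per metric.

## Evaluation metrics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), Jaccard TP/(TP+FP+FN),
Dice 2TP/(2TP+FP+FN) (= 2·JI/(1+JI), an identity the tests check to
machine precision). Two empty volumes score JI = DC = 1 (vacuous
agreement; needed for vessel-free slices in slice-wise Dice, and logged).
MHD is the maximum of the two directed mean nearest-neighbor distances
between boundary voxel sets (foreground voxels 6-adjacent to background;
26-adjacency available via config) and is reported in voxel units on
isotropic grids; MHD-CL applies the same statistic to rasterized
centerlines. Note that MHD of a shape shifted along its own axis of
symmetry is much smaller than the shift, since most points coincide —
the metric measures set proximity, not displacement.

## The phantom generator

Vessels are swept spheres along smooth curves: a straight chord plus a
sinusoidal perpendicular perturbation windowed to vanish at the endpoints,
with curvature bounded so tubes never self-intersect. Rasterization marks
voxels whose centers lie within the radius of the densely sampled
polyline (0.3 µm steps), so analytic centerlines, radii, lengths and
end-to-end distances remain exact ground truth. Rejection sampling keeps
tube surfaces at least 2 µm apart (closer tubes can touch diagonally after
voxelization). Default study conditions: 64³ volume at 1 µm³, five
vessels of radius 2–5 µm, tortuosity amplitude 3 µm, 2 RBC shadows per
100 µm of centerline, Gaussian noise σ = 0.05 on a 0.1/0.9
background/foreground intensity scale, contrast halving every 150 µm of
depth, and per-slice jitter up to 3 px.

Degradations: RBC shadows are Poisson-sampled along centerlines and
rendered as dark ellipsoids (streak half-length 2–4 µm, cross radius
0.75·r) strictly inside the lumen — the truth mask never changes. Depth
decay multiplies foreground-background contrast by `0.5^(depth/L)`. Slice
motion draws an independent in-plane translation per slice (each slice is
a separate acquisition), scaled so the largest magnitude equals the stated
bound, with slice 0 fixed; the applied fields are returned for recovery
testing.

What the phantoms do **not** emulate: the microscope point-spread
function, photon shot noise statistics, time-resolved flow, vessel radius
variation along a segment, and true vascular network topology (loops and
trees beyond the explicit fixtures). Passing the phantom-recovery tests
therefore demonstrates the pipeline's correctness and internal
consistency, not its accuracy on real angiograms — the published
real-data accuracy figures require the original annotated dataset and
GPU-month-scale fine-tuning, which are out of scope here.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so the full
pipeline exercises every stage on one CPU core: 64³ phantom, 2,000
training patches, minibatch 256 with early stopping (~10 epochs), full
tiled inference, and a 32-slice registration phantom. The end-to-end
segmentation recovery criterion (Dice ≥ 0.80 against the truth mask) is
met with a wide margin (≈ 0.92–0.94) under these conditions.
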