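# Methods

`leafletseg` implements a semi-automatic pipeline for segmenting the three
tricuspid valve (TV) leaflets — anterior, posterior, septal — from 3D
transthoracic echocardiography (3DE), with the hypoplastic-left-heart
population in mind: a fully convolutional network consumes a valve-centred
multi-channel volume and produces a four-class label map (background + three
leaflets).  The "semi-automatic" part is the user-supplied anatomy: an
annular curve, A/P/S/L quadrant landmarks, and ASC/PSC/APC commissural
landmarks, placed in 3D Slicer and read from FCSV or markups-JSON files.

## Preprocessing

**Valve coordinate frame.**  The frame is built from the A and L landmarks
and the centroid of all four quadrant points: the origin is the APSL
centroid, x points toward L, y toward A (orthogonalised against x), and
z = x × y approximates the annular-plane normal.  The exact axis labelling
is a package convention; any fixed convention works provided it is applied
consistently to images, labels, curves and landmarks, which the round-trip
and equivariance tests enforce.

**Spacing rule.**  Volumes are resampled isotropically at
`spacing = min(0.25 mm, h / 6)`, where `h` is the thinnest leaflet's extent
along the valve z axis: a hard 0.25 mm cap, decreased when needed so the
thinnest leaflet spans at least 6 voxels.  `h` is measured as the spread of
the leaflet's voxel centers projected on the valve axis — leaflets are thin
roughly parallel to the annular plane, so this is the binding dimension.
The reoriented case is placed in a fixed ROI (224³ by default) with the
APSL centroid at the ROI centre; images are interpolated linearly, labels
nearest-neighbor, out-of-field voxels are zero-filled.  In the
"no resampling" variant the native spacing is kept and only the
reorientation and ROI placement are applied.  An annulus that does not fit
the ROI logs a warning rather than failing.

**Ground-truth cleanup.**  Per leaflet label: keep the largest 26-connected
island, then fill holes with an iterative voting filler (radius 1, majority
rule, at most 20 iterations; SimpleITK's
`VotingBinaryIterativeHoleFillingImageFilter`).  The connectivity and filler
parameters are package conventions.  Cleanup is idempotent and applies to
ground truth only; at inference time only the largest-island step is used.

## Input encoding

The network input is 1–15 channels, always including the mid-systolic (MS)
frame:

* frames — Single-Phase (MS), Two-Phase (MS, MD), Four-Phase (ES, ED, MS,
  MD), or CSP: the 11-frame consecutive-systolic-phases window MS±5, which
  requires the MS index to sit at least five frames from both sequence ends;
* optionally one annulus channel: the closed curve rasterized as a tube
  (radius 0.5 mm) and converted to a signed distance map (SDM);
* optionally three commissure channels: ASC, PSC, APC spheres (radius
  1.0 mm), each converted to an SDM, in fixed order.

SDMs store each voxel's Euclidean distance in **mm** (not voxels) to the
structure's boundary voxels, negative inside — physical units keep the
channel meaning stable across the non-resampled variant where spacing
varies.  Every channel, image or SDM, is independently min-max normalized
to [0, 1]; a constant channel maps to zeros to avoid 0/0.  The full
configuration space is 4 frame modes × annulus on/off × commissures on/off
× resampling on/off = 32 configurations in four user-input groups of eight.

## Network

A modified V-Net: per encoder stage a residual convolution block (one conv
at stage 1, up to three deeper), then a 2³ stride-2 convolution that doubles
the filters and halves each spatial dimension; the decoder mirrors this with
2³ transposed convolutions and skip concatenation; a 1³ head yields
four-class logits, softmaxed per voxel.  All trunk kernels are 3×3×3 and all
non-linearities ReLU, with instance normalization inside the blocks.  Two
profiles are exercised: the full profile (5 stages, 16 base filters, 224³
input) and a desk profile (2 stages, 8 base filters, 32–64³ input) used
throughout the tests.

The network, backpropagation, and the rectified-Adam optimizer are
implemented directly in numpy: convolutions via sliding-window BLAS
contractions, the non-overlapping stride-2 layers via block reshapes, and
analytically derived backward passes for every layer, verified against
central finite differences in float64.  Forward and backward passes are
deterministic given weights and input.

## Learning

Loss = 1.0 · SoftDice + 0.02 · weighted cross-entropy.  Soft Dice averages
`(2Σpg + ε)/(Σp + Σg + ε)` over the four classes.  The CE weight of voxel v
is a class term plus a border term: `rebal(label(v)) + ω₀·[d(v) < d₀]` with
ω₀ = 50 and d₀ = 3 voxels, where d is the Euclidean distance to the nearest
boundary voxel (a voxel 6-adjacent to a differently labeled voxel,
background counting as a label; strict inequality).  Class rebalancing
(inverse label frequencies normalized to sum to one) is available but off
by default, in which case the class term is the uniform constant 1/4 so the
CE remains a proper weighted mean.  The CE probability is clipped at 1e-7.

Optimization: RAdam, learning rate 0.02, weight decay 1e-5 (L2 folded into
the gradient), batch size 2 (full profile) or 4 (desk).  A seeded 10%
validation split (at least one case) drives a halve-on-plateau scheduler
(patience 3 epochs) and early stopping (patience 30, cap 200 epochs);
"validation performance" is the validation composite loss.  The checkpoint
with the best validation loss is returned.

Augmentation (each transform firing independently with probability 0.5,
applied identically to every channel and to the labels): random affine with
rotation ±30° per axis, translation ±50 voxels, scaling ±0.3; contrast
adjustment ±0.3 and 2nd/99th-percentile histogram clipping on image channels
only; channels re-normalized to [0, 1] afterwards.  Elastic deformation is
deliberately absent.

## Inference

A single full-ROI forward pass on the same channel layout used in training;
per-voxel argmax with ties broken toward the lowest class index (favouring
background — a conservative convention).  Post-processing keeps only the
largest 26-connected component per leaflet and never adds voxels.

## Evaluation and statistics

DSC is `2|P∩Q|/(|P|+|Q|)`; both-empty comparisons are reported as missing
rather than scored.  MBD is the symmetrized mean nearest-**vertex** distance
between raw marching-cubes surfaces (vertices in physical mm).  Because
vertices, not triangles, are matched, mesh resolution bounds the metric:
translations beyond the vertex-lattice period alias onto neighbouring
vertices and MBD is guaranteed monotone in the offset only for
sub-vertex-spacing displacements.  Scores are reported per leaflet, as the
three-leaflet average (computed per case before summarizing), and for the
merged single-label valve; a leaflet missing from a prediction is flagged
and excluded from the average.

Configurations are ranked per case by leaflet-average MBD (rank 1 = lowest,
ties averaged); the winner has the lowest mean rank.  Pairwise comparisons
use the two-sided Wilcoxon signed-rank test (zero differences dropped; exact
null for ≤ 25 effective pairs, normal approximation with continuity
correction beyond), with median [IQR] summaries (linear-interpolation
quantiles, 2 decimals) and a 0.05 significance threshold without
multiplicity correction.

## Synthetic phantoms

The generator emulates the geometry and imaging statistics the pipeline
assumes: a saddle-shaped elliptical annulus (z = h·cos 2θ), three thin
billowed leaflet patches swept from the annulus to a central coaptation
zone, meeting at commissures that partition the circle; multi-frame
open/close dynamics following a smooth phase curve centred on the MS frame;
bright leaflets over a mid-gray myocardial band and dark blood pool;
multiplicative clipped-Gaussian speckle; optional spherical signal-dropout
holes that may intersect leaflets.  Labels are rasterized before noise, so
the ground truth is exact by construction (surfaces are analytic,
thresholded at half the leaflet thickness).

Defaults: annulus semi-axes 9 × 8 mm, saddle 1.5 mm, leaflet thickness
2.4 mm, billow 2.5 mm, sectors 130/110/120°, 11 frames with MS at index 5,
maximum orifice opening fraction 0.5, speckle σ = 0.08, 64³ grid at 0.4 mm.
The thickness default makes leaflets span 6 voxels on the phantom grid —
the same minimum height the preprocessing rule guarantees on clinical data —
and the 11-frame/MS=5 default is the smallest sequence satisfying the CSP
window.  Datasets jitter the annulus axes, saddle, billow and sector split
by bounded uniform perturbations with per-case derived seeds.

What the phantoms do **not** emulate: ultrasound physics (no point-spread
function, ray-dependent attenuation or anisotropic speckle), chordae or
papillary structure, stitch artifacts, or anatomical shape variation beyond
the jittered ellipse.  Passing phantom tests therefore demonstrates that the
machinery — geometry handling, encoding, optimization, metrics — is correct
and that the network can learn thin-structure segmentation at desk scale;
it says nothing about accuracy on clinical echocardiograms.

## Problem sizes and numerical choices

The test suite runs the desk profile end to end: 10 phantoms (8 training,
2 held out) resampled to a 48³ ROI at 0.55 mm, Single-Phase + annulus +
commissures input (5 channels), 60-epoch cap — chosen as the smallest
setting in which the model cleanly overfits the phantom anatomy (training
leaflet-average DSC ≥ 0.85, held-out merged DSC ≥ 0.7 under the fixed
seeds).  Tolerances: orthonormality checks at 1e-9; SDM oracle agreement
within half a voxel diagonal (rasterization bound); loss-gradient
finite-difference checks at 1e-3 relative (float64); DSC oracle agreement
exact.  Degenerate inputs fail loudly: coincident or collinear landmarks,
open annular curves, empty masks for SDMs or surfaces, all-zero CE weights,
and CSP windows without five frames on each side of MS all raise errors
naming the offending input.

## Known limitations

* MBD accuracy is bounded by mesh resolution (vertex matching, see above).
* Full-profile (224³, 5-stage) training is computationally out of reach of
  the pure-numpy implementation; the full profile is provided for
  completeness and correctness is established at desk scale.
* The spacing rule needs ground-truth labels to measure leaflet height, so
  fully label-free preprocessing of new cases must reuse a spacing chosen
  on annotated data.
* Hole filling at inference is deliberately not performed; signal-dropout
  holes in predictions are left to downstream adjudication.
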