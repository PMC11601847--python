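# Methods

This note documents the models, conventions and numerical choices behind
`bootseg`, including the places where the design was genuinely open and the
package fixes one documented behavior.

## Conventions

Axis order is `(z, y, x)` with 0-based voxel indices and half-open bounding
boxes; physical coordinates are `offset + index * voxel_size` in
nanometres. Anisotropy is expected (serial sections: z spacing coarser than
in-plane), default voxel size `(40, 8, 8)` nm. Sparse annotations follow
the rule *unlabeled ≠ background*: a sparse label volume always travels
with a boolean annotation mask marking voxels whose state is known. The
mask produced by `subsample_labels` covers the kept instances plus an
`r`-voxel dilated collar (default `r = 2`), approximating background a
human annotates along drawn boundaries; how real annotation tools encode
annotated background varies, so this convention is a package choice.
2D annotations are depth-1 3D volumes — one code path for both cases.

## Training targets

**Affinities.** Channel `c` at voxel `v` is the connectivity of `v` to
`v + offset_c` for the three unit offsets: 1 iff both voxels carry the same
nonzero ID. Background pairs are 0 — background is "no object", which is
what lets the watershed leave it unsegmented. Out-of-bounds relations are 0.

**Local shape descriptors.** For each foreground voxel, Gaussian-weighted
statistics of its own-label mask, window truncated at 3σ (σ in nm, default
48): 3D layout `[mean-offset z,y,x | covariance diag | pairwise
correlations zy,zx,yx | size]` (10 channels), 2D per-section layout
`[mean-offset y,x | cov diag | correlation | size]` (6 channels). Exact
normalizations (package choices, fixed and tested against a brute-force
oracle at 1e-5): mean offsets map `[-3σ, 3σ] → [0, 1]` with 0.5 = zero
offset; variances are divided by `(3σ)²`; Pearson correlations map
`[-1, 1] → [0, 1]`; size is the Gaussian-weighted fraction of the window
covered by the mask. Implemented with separable sampled-Gaussian
correlations (sum-normalized kernels, zero boundary), so the convolution
route agrees with the direct per-voxel definition to float precision.

**Masked weighted MSE.** `L = Σ w (ŷ − y)² / max(Σ w, ε)`. Normalizing by
the weight total (not voxel count) keeps sparse and dense batches on one
loss scale. The gradient is identically zero wherever `w = 0`; this is the
contract that confines supervision to annotated voxels and is verified
numerically in the tests. Whether the loss should additionally
class-balance boundary vs interior voxels inside the mask is not forced:
both `uniform` (default) and `balanced` modes exist.

## Synthetic training data

The 2D-stack→3D network trains exclusively on synthetic volumes, generated
per step. The recipe (a documented package design; only standard
image-processing and morphological operations): smoothed Gaussian noise is
rank-normalized into an elevation landscape; a compact watershed
(compactness 0.02) from `n ~ U{8..20}` random seeds partitions the volume
into convoluted, space-filling basins; one voxel of each inter-basin face
is carved to background, producing thin membrane-like walls; a smooth
random in-plane deformation (amplitude 1.5 px, field scale 12 px, varying
along z) convolves the shapes; 6-connected components are relabeled,
fragments under 64 voxels dropped, and split-offs beyond the configured
count trimmed (largest kept). Consequences used elsewhere: every instance
is one 6-connected (hence 26-connected) component and no two instances
share a voxel face, so the labels are exactly recoverable from
direct-neighbor affinities — the basis of the round-trip test.

Simulated stacked 2D predictions are per-section 2D LSDs degraded, in this
fixed order and independently per section: integer in-plane shift in
`[-1, 1]` px (mis-alignment), additive Gaussian noise (σ = 0.03, clipped to
[0, 1]), whole-section dropout with probability 0.05 (lost sections). The
raw-image simulator gives instances individual mean intensities, darkens
walls by 0.5, and adds a low-frequency intensity field plus noise.

What the generator does *not* emulate: real EM texture (organelles,
vesicles), imaging artifacts beyond additive noise, true neurite
morphology (long thin processes spanning many sections), and annotation
inconsistency. Passing tests therefore demonstrate that the machinery is
correct and that the learning problems are solvable at desk scale — not
that the defaults transfer to any particular real dataset.

## Networks

No GPU framework is used: the 2D and 3D U-Nets are implemented directly on
numpy (same-padded 3^d convolutions as sums of shifted matmuls, ReLU,
average-pool down / nearest-neighbor up with a skip concatenation, sigmoid
heads, Adam at 2e-3). Two resolution levels, 8 base features; the 3D nets
pool `(1, 2, 2)` so the coarse z axis is preserved. These sizes are chosen
so that every 500-iteration training stage finishes in about two minutes on
one CPU core; they are demonstration-scale stand-ins for the larger U-Nets
a production run would use, with the same inputs, outputs and losses.

The three training stages:

* `train_sparse_2d` — fields of view are sampled with rejection toward the
  annotation mask (≥ 5% annotated voxels per patch by default), augmented
  (flips, transpose, intensity; optional elastic), and 2D LSD targets are
  recomputed from the augmented label patch each step.
* `train_3d_synthetic` — a fresh synthetic pair per step, seeded from the
  training seed and step index; supervises the affinity head only; never
  consumes raw images.
* `train_mtlsd_3d` — dense pseudo-ground-truth supervision of both heads,
  joint loss = affinity MSE + LSD MSE. Targets are precomputed once from
  the dense labels, so geometric augmentation is disabled (intensity-only);
  recomputing LSD targets per augmented 3D patch would dominate the step
  time at this scale.

Inference is overlap-tiled: each tile is evaluated with a zero-filled
context margin that covers the receptive field (rounded up to the pooling
factor, cores aligned to the pooling grid) and only the core is kept, so
any tiling gives bit-identical results. Training and inference are
deterministic under a fixed seed in a single-threaded run.

## Post-processing

Per-voxel pooling of affinities is the mean over all in-bounds incident
relations (each offset contributes to both endpoints; a symmetric choice).
The binary mask is `pooled > t`; the Euclidean distance transform
(anisotropy-aware, physical units) is seeded at local maxima with a minimum
physical separation (40 nm default, at least one seed per mask component);
watershed floods the negated distance within the mask with 6-connectivity.
The region adjacency graph stores per-fragment centers of mass and voxel
counts; edge scores are the mean affinity over the boundary voxel pairs.
Agglomeration processes edges by decreasing score, merging while the score
is at least the merge threshold `m`; after a merge, parallel edges combine
by summing their affinity sums and pair counts, so a cluster-pair score is
always the boundary mean over the union — equivalent to truncating the
merge hierarchy at `m`, and verified against an exhaustive oracle. Ties
break by ascending node-ID pair; seeds are numbered lexicographically; the
chain is fully deterministic.

Three default operating points exist deliberately. The library default
(`t = 0.1`, `m = 0.5`) targets near-binary affinities: any foreground voxel
with one confident same-object neighbor (pooled ≥ 1/6) stays in the mask,
giving exact label recovery for wall-separated volumes. The bootstrap
calibrates its two inference stages separately, reflecting how differently
the two networks respond: the 2D→3D chain produces mid-range boundary
responses (pseudo-ground-truth stage: `t = 0.4`, `m = 0.7`), while the
multi-task net is sharply bimodal (interiors ≈ 0.95, boundaries ≈ 0.16)
with residual smear at missed interfaces, so only a high merge threshold
separates them (final stage: `t = 0.4`, `m = 0.9`). Both points were fixed
from the boundary/interior response ranges of the trained demonstration
nets. `grid_search` is the general mechanism for choosing these parameters
against a reference labeling (VOI or edit-count objective, deterministic
lexicographic tie-break); the bootstrap itself runs ground-truth-free,
hence fixed defaults. The minimum-segment-size filter defaults to off: the
strict size filter belongs to ground-truth preparation, not predictions.

## Evaluation

Ground truth is prepared by splitting every label into 26-connected
components, removing components with strictly fewer than 500 voxels, and
relabeling contiguously. VOI is reported in bits over ground-truth
foreground voxels: `voi_split = H(seg|gt)`, `voi_merge = H(gt|seg)`.

Skeletons: per object, 3D topological thinning on the voxel grid followed
by a minimum-spanning-tree graph over 26-adjacent skeleton voxels with
physical edge lengths (the MST avoids diagonal double-counting in thick
junctions; disconnected thinning artifacts are re-joined at their closest
node pair). Thinning on the anisotropic grid rather than an isotropically
resampled one is a simplification; externally curated skeletons can be
supplied as SWC files and bypass this step entirely.

Edit counts: each skeleton node maps to the segment under its coordinates
(nodes on background are ignored by default — a policy choice).
*Splits* per object = (number of connected skeleton islands induced by
grouping that object's nodes by segment ID) − 1. *Merges* per segment
containing k > 1 objects = the minimum number of edges whose removal
separates the k objects in the within-segment node adjacency graph
(skeleton edges plus bridging edges between 26-adjacent nodes of different
objects): exact max-flow for k = 2, exact subset enumeration up to 16
edges, isolating-cut heuristic (≤ 2−2/k of optimum) beyond that. If two
co-resident objects have no connecting path the cut contribution is zero.
Totals are normalized per ground-truth object and per micrometre of total
skeleton path length.

## Bootstrap orchestration

Six resumable stages (2D training, 3D-synthetic training, pseudo-GT
generation, multi-task training, volume-1 segmentation, LSD error map) each
write artifacts plus a manifest entry keyed by a hash of the full
configuration; reruns skip stages whose artifacts and hash match, and a
failed stage is recorded before the error propagates. Stage seeds derive
from the master seed by hashing the stage name, so stages are independently
reproducible. The pseudo ground truth is consumed exactly as produced —
dense, unmasked, unproofread. One bootstrapping round is the default;
the LSD error map is produced for proofreading guidance, and binary opening
of the thresholded map (ball/disc element) suppresses the thin boundary
shells that reflect pixel-level boundary disagreement rather than real
morphology errors.

## Problem sizes

The shipped demonstrations and checks use 64³ voxel volumes (5–30
instances), patches of 64² (2D) and 16×32×32 (3D), 500 training iterations
per stage, and 20-seed round-trip batches — sizes chosen so the complete
suite runs on a single CPU core in well under half an hour while still
exercising every stage end to end.

## Known limitations

* The U-Nets are demonstration-scale; real EM volumes need deeper nets,
  GPU training and blockwise processing, none of which are in scope.
* Long-range/mutex affinities, multicut partitioning, auto-context
  (raw + predictions as 3D-net input) and iterative multi-round refinement
  are out of scope.
* The synthetic morphology is space-filling but not neurite-like
  (see above), and the skeletonization is a stand-in; metric *definitions*
  are exact, their inputs on real data deserve curated skeletons.
* Exact merge-edit counting is exponential and only applied to small
  per-segment graphs; large merged bodies fall back to the isolating-cut
  bound.
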