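# Methods

## Model and assumptions

`slicelink` treats 3D reconstruction from serial-section segmentations as a
grouping problem over 2D segments: each slice contributes a set of
connected foreground regions, and a 3D object is an equivalence class of
segments linked across slices. The method assumes

* in-plane resolution is much finer than the section thickness, so a 3D
  structure appears as a chain of 2D cross-sections rather than as an
  isotropic voxel blob;
* structures are sparsely distributed, so bounding-box overlap between
  segments of *different* objects is rare — this is what makes the box-IoU
  prefilter cheap and the shape term safe (a shape term with no sparsity
  would happily match any two similar cross-sections whose boxes graze);
* 2D segmentation quality is taken as given; the linker never edits masks.

Coordinates are (z, y, x), 0-based; bounding boxes are half-open; label 0
is background. In-plane connectivity is 8-connectivity (blob-like organelle
masks routinely touch diagonally); it is configurable per call. Both binary
and pre-labeled per-slice masks are accepted — a labeled value whose
support is disconnected is split into its components, and segments are
ordered by their first pixel in row-major scan order so all matrix indices
are deterministic.

## The similarity and its parameters

A candidate pair is scored coarsely by bounding-box IoU and, in the
uncertain band `[t_low, t_high)`, re-scored as

    c = (P^2 + lam * S^2) / (1 + lam)

with `P` the in-place mask IoU and `S` the best mask IoU after scaling and
translating one segment. Binary connections require `c > t_fine`
(strictly). Parameters, defaults and rationale:

| parameter | default | meaning |
|---|---|---|
| `t_low` | 0.01 | below: certain rejection. Small, because a false rejection is unrecoverable; raising it trades recall for speed. |
| `t_high` | 0.4 | above: accept without pixel validation. |
| `t_fine` | 0.03 | threshold on the validated similarity; larger values split, smaller values merge. |
| `lam` | 0.5 | position/shape balance. 0.5 for blob-like data whose sections overlap strongly (position term dominant); 2 for sheet-like data whose sections drift with little or no overlap (shape term dominant). Presets `LinkParams.mitochondria()` / `LinkParams.synapse()`. |
| `transforms` | see below | the finite search set H for the shape term. |
| `skip_enabled` | True | bridge single missing slices. |

All thresholds are dimensionless IoU-scale quantities in [0, 1].

**The transform set H.** The shape term is defined over transformations of
the form scale-then-translate; the cardinality and range of the set are a
free design choice. The default searches a geometric scale ladder
{0.80, 0.90, 1.00, 1.11, 1.25} augmented with the equivalent-diameter
ratio of the two segments (so a uniformly grown or shrunk section still
scores ≈ 1), each combined with exact centroid alignment plus a ±1 px
local refinement per axis; the identity transformation is always a member,
which guarantees `S ≥ P`. A small local search keeps validation cost
bounded (≤ 31 mask IoUs per validated pair) while making pure-translation
and moderate-scale pairs score near 1. Scaling rasterizes by
nearest-neighbour inverse mapping about the segment centroid; half-pixel
ties round away from zero, a fixed rule that keeps results deterministic.

**Degenerate mode.** `LinkParams.connected_components()` sets `lam = 0`,
`t_fine = 0`, `t_low = 0`, `t_high = 1` and disables skip. With those
values an entry survives iff the two pixel sets overlap, so the pipeline
reproduces 3D connected-component labeling by pixel overlap exactly.
`t_high = 1` is part of this mode because accepted coarse entries
(`c ≥ t_high`) deliberately bypass pixel validation: with any smaller
`t_high` a pair with high box IoU but zero pixel overlap would connect in
the pipeline but not in the voxel-level reference. The reference itself
(`baseline.cc3d_overlap`) uses overlap (face) connectivity in z rather
than 26-connectivity: the pipeline's box-IoU > 0 gate can only ever see
true overlap, so diagonal-touch-only joins are outside both methods by
construction.

## Forward labeling

Categories are recomputed per binary matrix from its row sums R and column
sums N: `R=0 → E`, `R≥2 → S1` on rows; `N=0 → S`, `N≥2 → M2` on columns;
per edge, `R=1,N=1 → O`, `R=1,N≥2 → M1` on the row and `R≥2,N=1 → S2` on
the column; first-slice segments are additionally S and last-slice
segments E. Seeds (S/S2/M2) receive fresh labels in (slice, segment)
order; labels flow along one-to-one chains; split/merge edges union their
endpoint labels. The pairwise "reassign min(j1, j2)" rule is
order-dependent unless closed transitively, so the union is implemented as
a disjoint-set forest whose representative is the minimum label — the
unique transitive closure, independent of edge order. The final partition
provably equals the connected components of the segment graph with edge
set {B entries} ∪ {accepted skip pairs}; the test suite checks this
against an independent graph library on randomized stacks.

Skip connection considers only pairs (ending segment on slice i, starting
segment on slice i+2) with positive box IoU, where ending/starting status
is read from the adjacent matrices themselves (row sum 0 in B^i, column
sum 0 in B^{i+1}); each candidate is validated with the same combined
similarity and accepted strictly above `t_fine`. Stack-boundary
starts/ends play no role because no slice i+2 exists for them. Only
single-slice gaps are bridged; wider gaps are out of scope.

## Synthetic data generator

The generator produces stacks with known ground truth in two families:

* **blob** — filled ellipses (semi-axes 8–11 × 7–9 px) with a per-slice
  size jitter (`scale_jitter`, default ±5 %) and an integer centroid random
  walk (`drift_px`, default 2 px/slice): the large-overlap regime where
  the position term suffices.
* **sheet** — thin rotated rectangles (30–60 × 3–6 px) whose consecutive
  sections are exact integer-translated copies, alternating a fixed
  "zigzag" offset of ≈ 0.55 × length along the sheet axis plus
  ⌈thickness/2⌉ across. This makes the in-place overlap of consecutive
  sections deliberately weak (P² below the default `t_fine`) while the
  shape term is exactly 1 — the regime in which only `lam > 0` holds
  chains together, which is what the sheet recovery tests demonstrate.

Objects are confined to disjoint grid cells sized from the worst-case
shape extent plus trajectory excursion, with the anchor clamped so no
trajectory can leave its cell. Distinct objects therefore never share
bounding-box overlap — the generator's realization of the sparsity
assumption. Injected events: a *split* (one section branching into two
disjoint lobes that continue to the object's end), a *merge* (two lobes
joining), and single-slice *gaps* (one section deleted). Blob lobes are
0.38-scale copies tucked inside the parent footprint at ± half the
parent's x semi-axis, so lobe–parent pairs always reach validation and
pass on the combined term; sheet branches are the two halves of the parent
rectangle (3 px gap), placed so the transition sections lie inside the
parent footprint. Gap carriers are reserved before events are drawn —
one gap per otherwise event-free object at an interior slice — so each gap
breaks exactly one chain: with skip connection disabled the pipeline
reports exactly one split error per gap, with it enabled none. All
randomness flows from a single seeded NumPy generator; identical configs
give bit-identical stacks.

What the generator does **not** emulate: boundary noise on masks,
segmentation errors, touching objects, EM texture, registration artifacts,
gaps wider than one slice. Passing recovery tests therefore show that the
linking logic is correct under the stated geometry and sparsity
assumptions, not that the method is robust to arbitrary real-world
segmentation quality.

## Numerical and design choices

* Pixel-set operations encode (y, x) into sorted int64 keys and use
  `numpy.intersect1d`; a guard offset keeps moderately negative transformed
  coordinates encodable.
* Interval endpoints follow the screening definition exactly: closed at
  `t_high`, half-open at `t_low`, strict `>` at `t_fine` (an entry exactly
  equal to `t_fine` is rejected).
* The shape term short-circuits once it reaches 1 and is skipped entirely
  at `lam = 0`.
* Raising `t_fine` can only remove edges, so the object count is
  monotonically non-decreasing in `t_fine`; violated monotonicity would
  indicate a bug and is tested.
* Label volumes are written at the smallest unsigned dtype that holds the
  maximum label (promoting through uint8/16/32/64, never truncating).
* Empty inputs degrade gracefully: an all-background stack yields an empty
  partition and an empty object table.

## Problem sizes used in tests and the acceptance script

Equivalence and oracle checks run 50 stacks each (≤ 24 slices, 128 × 128,
2–4 objects with splits/merges/gaps; plus 8 sheet stacks at 400 × 400).
Recovery runs 3 stacks of 30 blob objects (12 × 256 × 256) and 3 stacks of
4 sheet objects (10 × 400 × 400); the gap check uses 6 blob objects with
1–3 gaps. These sizes exercise every connection case while keeping the
whole suite in the tens of seconds; all properties are scale-free, so
larger frames only add pixels, not cases.

## Known limitations

* Skip connection bridges exactly one missing slice; two consecutive
  missing slices split an object irrecoverably.
* The shape term searches scaling and translation only — no rotation or
  shear — so a section that rotates sharply between slices can fall below
  threshold on sheet-like data.
* Dense, touching structures violate the sparsity assumption; bounding-box
  screening then produces many validation candidates, and shape-based
  validation can merge look-alike neighbours.
* Error counts are reported as excess pieces (a k-way split counts k−1);
  other conventions count each fragmented object once regardless of
  multiplicity.
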