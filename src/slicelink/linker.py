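"""Forward coarse-to-fine linking of per-slice segments into 3D objects.

Stages, for an n-slice stack:

1. *Coarse screening*: sparse matrices C^i of bounding-box IoU between the
   segments of slices i and i+1 (boxes disjoint => segments disjoint, so
   zeros are exact rejections).
2. *Validation*: entries in the uncertain band [T_l, T_h) are recomputed
   from the pixel masks with the position/shape similarity; thresholding
   (strictly above T_s) yields binary connection matrices B^i.
3. *Fine connection*: per-segment categories from the row/column sums of
   B^i — One-to-one (O), Start (S), End (E), Split parent/children
   (S1/S2), Merge parents/child (M1/M2) — then forward labeling: every
   S/S2/M2 segment seeds a fresh label, labels flow along O chains, and
   split/merge edges union their endpoint labels (min label wins).
4. *Skip connection*: an ending segment on slice i and a starting segment
   on slice i+2 whose boxes overlap are validated the same way and, if
   accepted, unioned — bridging a single damaged/missing slice.

The result is a disjoint partition of all 2D segments; each group is one
3D object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .components import Segment2D, bbox_iou, extract_segments
from .labels import LabelAssignment
from .similarity import LinkParams, ScreeningCase, classify_coarse, refined_similarity

__all__ = [
    "Category",
    "ConnectionMatrix",
    "LinkResult",
    "coarse_matrices",
    "refine_matrix",
    "assign_categories",
    "forward_label",
    "skip_connect",
    "run_pipeline",
]

# Category codes: One-to-one, Start, End, Split parent, Merge parent,
# Split child, Merge child.
class Category:
    O = "O"
    S = "S"
    E = "E"
    S1 = "S1"
    M1 = "M1"
    S2 = "S2"
    M2 = "M2"


@dataclass
class ConnectionMatrix:
    """Sparse k_i x k_{i+gap} similarity matrix between two slices."""

    slice_index: int
    gap: int  # 1 = adjacent (C^i / B^i), 2 = skip (C^{i,2})
    shape: tuple[int, int]
    entries: dict[tuple[int, int], float] = field(default_factory=dict)

    def row_sums(self) -> np.ndarray:
        r = np.zeros(self.shape[0], dtype=np.int64)
        for (p, _q) in self.entries:
            r[p] += 1
        return r

    def col_sums(self) -> np.ndarray:
        n = np.zeros(self.shape[1], dtype=np.int64)
        for (_p, q) in self.entries:
            n[q] += 1
        return n

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.entries)


def _pairwise_bbox_iou(
    segs_a: list[Segment2D], segs_b: list[Segment2D]
) -> dict[tuple[int, int], float]:
    if not segs_a or not segs_b:
        return {}
    a = np.array([[s.bbox.x0, s.bbox.y0, s.bbox.x1, s.bbox.y1] for s in segs_a])
    b = np.array([[s.bbox.x0, s.bbox.y0, s.bbox.x1, s.bbox.y1] for s in segs_b])
    iw = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    ih = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    inter[(iw <= 0) | (ih <= 0)] = 0
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    ps, qs = np.nonzero(inter > 0)
    return {
        (int(p), int(q)): float(inter[p, q] / union[p, q]) for p, q in zip(ps, qs)
    }


def coarse_matrices(
    segments: list[list[Segment2D]], gap: int = 1
) -> list[ConnectionMatrix]:
    """Coarse (box-IoU) connection matrices for slice pairs (i, i+gap)."""
    if gap not in (1, 2):
        raise ValueError("gap must be 1 or 2")
    n = len(segments)
    out = []
    for i in range(max(n - gap, 0)):
        entries = _pairwise_bbox_iou(segments[i], segments[i + gap])
        out.append(
            ConnectionMatrix(
                slice_index=i,
                gap=gap,
                shape=(len(segments[i]), len(segments[i + gap])),
                entries=entries,
            )
        )
    return out


def refine_matrix(
    coarse: ConnectionMatrix,
    segs_a: list[Segment2D],
    segs_b: list[Segment2D],
    params: LinkParams,
) -> ConnectionMatrix:
    """Binary fine-connection matrix B from a coarse matrix.

    CONNECT entries pass without pixel validation; NONE entries are
    dropped; VALIDATE entries are replaced by the refined similarity and
    kept only if strictly above T_s.
    """
    entries: dict[tuple[int, int], float] = {}
    for (p, q), c in coarse.entries.items():
        case = classify_coarse(c, params)
        if case is ScreeningCase.CONNECT:
            entries[(p, q)] = 1.0
        elif case is ScreeningCase.VALIDATE:
            r = refined_similarity(segs_a[p], segs_b[q], params)
            if r > params.t_fine:
                entries[(p, q)] = 1.0
    return ConnectionMatrix(
        slice_index=coarse.slice_index, gap=coarse.gap, shape=coarse.shape, entries=entries
    )


def assign_categories(
    b_matrices: list[ConnectionMatrix], k_per_slice: list[int]
) -> dict[tuple[int, int], set[str]]:
    """Per-segment category sets from the binary matrices' row/column sums.

    For B^i with row sums R and column sums N: R=0 -> E, R>=2 -> S1 on the
    row; N=0 -> S, N>=2 -> M2 on the column; per edge (p, q): R_p=1, N_q=1
    -> O on the row; R_p=1, N_q>=2 -> M1 on the row; R_p>=2, N_q=1 -> S2
    on the column.  Every first-slice segment additionally gets S and every
    last-slice segment gets E.  A segment may hold several categories.
    """
    n = len(k_per_slice)
    if n >= 2 and len(b_matrices) != n - 1:
        raise ValueError("need one adjacent matrix per slice pair")
    cats: dict[tuple[int, int], set[str]] = {
        (i, p): set() for i in range(n) for p in range(k_per_slice[i])
    }
    if n == 0:
        return cats
    for p in range(k_per_slice[0]):
        cats[(0, p)].add(Category.S)
    for p in range(k_per_slice[n - 1]):
        cats[(n - 1, p)].add(Category.E)
    for b in b_matrices:
        i = b.slice_index
        rows, cols = b.row_sums(), b.col_sums()
        for p in range(b.shape[0]):
            if rows[p] == 0:
                cats[(i, p)].add(Category.E)
            elif rows[p] >= 2:
                cats[(i, p)].add(Category.S1)
        for q in range(b.shape[1]):
            if cols[q] == 0:
                cats[(i + 1, q)].add(Category.S)
            elif cols[q] >= 2:
                cats[(i + 1, q)].add(Category.M2)
        for (p, q) in b.entries:
            if rows[p] == 1 and cols[q] == 1:
                cats[(i, p)].add(Category.O)
            elif rows[p] == 1 and cols[q] >= 2:
                cats[(i, p)].add(Category.M1)
            if rows[p] >= 2 and cols[q] == 1:
                cats[(i + 1, q)].add(Category.S2)
    return cats


_SEED_CATS = {Category.S, Category.S2, Category.M2}


def forward_label(
    k_per_slice: list[int],
    b_matrices: list[ConnectionMatrix],
    categories: dict[tuple[int, int], set[str]],
) -> LabelAssignment:
    """Forward labeling: seed S/S2/M2 segments in (slice, segment) order,
    propagate along one-to-one chains, then union split/merge edges."""
    assignment = LabelAssignment()
    raw: dict[tuple[int, int], int] = {}
    next_label = 1
    n = len(k_per_slice)
    for i in range(n):
        for p in range(k_per_slice[i]):
            if categories[(i, p)] & _SEED_CATS:
                raw[(i, p)] = next_label
                assignment.assign((i, p), next_label)
                next_label += 1
        if i < n - 1:
            b = b_matrices[i]
            rows, cols = b.row_sums(), b.col_sums()
            for (p, q) in b.sorted_edges():
                if rows[p] == 1 and cols[q] == 1:  # O chain continues
                    raw[(i + 1, q)] = raw[(i, p)]
                    assignment.assign((i + 1, q), raw[(i, p)])
    unlabeled = [
        (i, p) for i in range(n) for p in range(k_per_slice[i]) if (i, p) not in raw
    ]
    if unlabeled:  # must be impossible: every segment is a seed or O target
        raise RuntimeError(f"segments left unlabeled by forward pass: {unlabeled}")
    # Split/merge re-assignment: union parent label with each child label.
    for b in b_matrices:
        i = b.slice_index
        rows, cols = b.row_sums(), b.col_sums()
        for (p, q) in b.sorted_edges():
            if rows[p] == 1 and cols[q] == 1:
                continue  # already shared by propagation
            assignment.merge_labels(raw[(i, p)], raw[(i + 1, q)])
    return assignment


def skip_connect(
    assignment: LabelAssignment,
    segments: list[list[Segment2D]],
    b_matrices: list[ConnectionMatrix],
    params: LinkParams,
) -> tuple[LabelAssignment, list[tuple[int, int, int, float]]]:
    """Bridge single missing slices: for each ending segment on slice i and
    starting segment on slice i+2 with overlapping boxes, validate with the
    refined similarity and union if strictly above T_s.

    Ending/starting status comes from the adjacent matrices themselves
    (row sum 0 in B^i / column sum 0 in B^{i+1}); stack-boundary S/E play
    no role because no slice i+2 exists for them.

    Returns the updated assignment and the accepted pairs
    ``(i, p, q, similarity)``.
    """
    out = assignment.copy()
    accepted: list[tuple[int, int, int, float]] = []
    n = len(segments)
    for i in range(n - 2):
        rows = b_matrices[i].row_sums()
        cols = b_matrices[i + 1].col_sums()
        ending = [p for p in range(len(segments[i])) if rows[p] == 0]
        starting = [q for q in range(len(segments[i + 2])) if cols[q] == 0]
        if not ending or not starting:
            continue
        for p in ending:
            for q in starting:
                c = bbox_iou(segments[i][p].bbox, segments[i + 2][q].bbox)
                if c <= 0.0:
                    continue
                r = refined_similarity(segments[i][p], segments[i + 2][q], params)
                if r > params.t_fine:
                    out.merge((i, p), (i + 2, q))
                    accepted.append((i, p, q, r))
    return out, accepted


@dataclass
class LinkResult:
    """Everything the pipeline produced, for inspection and testing."""

    segments: list[list[Segment2D]]
    coarse: list[ConnectionMatrix]
    fine: list[ConnectionMatrix]
    categories: dict[tuple[int, int], set[str]]
    assignment: LabelAssignment
    skip_pairs: list[tuple[int, int, int, float]]
    objects: pd.DataFrame

    @property
    def n_objects(self) -> int:
        return self.assignment.n_objects


def run_pipeline(stack, params: LinkParams | None = None) -> LinkResult:
    """Full linking pipeline on a :class:`~slicelink.volume_io.SliceStack`.

    extract -> coarse screen -> validate/refine -> categories -> forward
    label -> skip connect; returns the disjoint partition plus per-object
    statistics.
    """
    from .volume_io import build_object_table  # local import to avoid cycle

    if params is None:
        params = LinkParams()
    segments = [
        extract_segments(stack.masks[i], slice_index=i) for i in range(stack.n_slices)
    ]
    k = [len(s) for s in segments]
    coarse = coarse_matrices(segments, gap=1)
    fine = [
        refine_matrix(c, segments[c.slice_index], segments[c.slice_index + 1], params)
        for c in coarse
    ]
    categories = assign_categories(fine, k)
    assignment = forward_label(k, fine, categories)
    skip_pairs: list[tuple[int, int, int, float]] = []
    if params.skip_enabled and stack.n_slices >= 3:
        assignment, skip_pairs = skip_connect(assignment, segments, fine, params)
    objects = build_object_table(segments, assignment, stack.voxel_size)
    return LinkResult(
        segments=segments,
        coarse=coarse,
        fine=fine,
        categories=categories,
        assignment=assignment,
        skip_pairs=skip_pairs,
        objects=objects,
    )
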