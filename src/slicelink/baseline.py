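"""Reference 3D connected-component labeling over a slice stack.

Two segments in adjacent slices are joined iff their pixel sets share at
least one (y, x) coordinate — overlap (face) connectivity in z.  This is
the classic whole-volume connected-components answer the linking pipeline
degenerates to at ``LinkParams.connected_components()``, and serves as the
equivalence target in tests.

Note this deliberately uses overlap connectivity, not 26-connectivity: the
pipeline's box-IoU > 0 criterion only ever detects true overlap, so
diagonal-touch-only joins are out of reach for both.
"""

from __future__ import annotations

import numpy as np

from .components import extract_segments
from .labels import LabelAssignment

__all__ = ["cc3d_overlap"]


def cc3d_overlap(stack) -> LabelAssignment:
    """3D connected components of a stack by slice-to-slice pixel overlap."""
    segments = [
        extract_segments(stack.masks[i], slice_index=i) for i in range(stack.n_slices)
    ]
    assignment = LabelAssignment()
    label = 1
    for segs in segments:
        for seg in segs:
            assignment.assign(seg.key, label)
            label += 1
    # Per-slice segment-index images; overlay adjacent pairs.
    h, w = (stack.masks[0].shape if stack.n_slices else (0, 0))
    prev = None
    for i, segs in enumerate(segments):
        idx = np.zeros((h, w), dtype=np.int32)
        for seg in segs:
            idx[seg.pixels[:, 0], seg.pixels[:, 1]] = seg.segment_index + 1
        if prev is not None:
            both = (prev > 0) & (idx > 0)
            if both.any():
                pairs = np.unique(
                    np.stack([prev[both], idx[both]], axis=1), axis=0
                )
                for p, q in pairs:
                    assignment.merge((i - 1, int(p) - 1), (i, int(q) - 1))
        prev = idx
    return assignment
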