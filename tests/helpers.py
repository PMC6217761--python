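"""Shared test utilities: fixture builders and independent oracles."""

from __future__ import annotations

import numpy as np

from slicelink.components import Segment2D, extract_segments
from slicelink.linker import LinkResult


def segments_of(mask, slice_index: int = 0) -> list[Segment2D]:
    return extract_segments(np.asarray(mask), slice_index=slice_index)


def seg(mask, slice_index: int = 0, index: int = 0) -> Segment2D:
    return segments_of(mask, slice_index)[index]


def mask_from_coords(coords, shape=(32, 32)) -> np.ndarray:
    m = np.zeros(shape, dtype=np.uint8)
    for y, x in coords:
        m[y, x] = 1
    return m


def random_blob_mask(rng: np.random.Generator, shape=(24, 24), n_blobs=1) -> np.ndarray:
    """A small random foreground mask (possibly several blobs)."""
    m = np.zeros(shape, dtype=np.uint8)
    for _ in range(n_blobs):
        cy = int(rng.integers(4, shape[0] - 4))
        cx = int(rng.integers(4, shape[1] - 4))
        ry = int(rng.integers(2, 5))
        rx = int(rng.integers(2, 5))
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        m[((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0] = 1
    return m


def pixel_iou_bruteforce(set_a, set_b) -> float:
    """Reference IoU by literal set counting over (y, x) tuples."""
    a, b = set(map(tuple, set_a)), set(map(tuple, set_b))
    if not a | b:
        return 0.0
    return len(a & b) / len(a | b)


def box_iou_bruteforce(a, b) -> float:
    """Reference bounding-box IoU by counting unit pixels of a raster."""
    xs = range(min(a.x0, b.x0), max(a.x1, b.x1))
    ys = range(min(a.y0, b.y0), max(a.y1, b.y1))
    in_a = in_b = in_both = 0
    for y in ys:
        for x in xs:
            pa = a.x0 <= x < a.x1 and a.y0 <= y < a.y1
            pb = b.x0 <= x < b.x1 and b.y0 <= y < b.y1
            in_a += pa
            in_b += pb
            in_both += pa and pb
    union = in_a + in_b - in_both
    return in_both / union if union else 0.0


def shape_term_bruteforce(
    seg_a: Segment2D,
    seg_b: Segment2D,
    alphas=None,
    shift_radius: int = 3,
) -> float:
    """Dense-grid maximization of the transformed-mask IoU.

    Independent of the library path: rescales seg_a's cropped mask with
    skimage's nearest-neighbour resampler for every alpha on a dense grid,
    then exhaustively tries integer placements around seg_b's centroid and
    takes the best plain set IoU.
    """
    from skimage.transform import rescale

    if alphas is None:
        alphas = np.linspace(0.7, 1.45, 76)
    b = set(map(tuple, seg_b.pixels))
    by, bx = seg_b.centroid
    crop = np.zeros((seg_a.bbox.height, seg_a.bbox.width), dtype=float)
    crop[seg_a.pixels[:, 0] - seg_a.bbox.y0, seg_a.pixels[:, 1] - seg_a.bbox.x0] = 1.0
    best = pixel_iou_bruteforce(seg_a.pixels, seg_b.pixels)
    for alpha in alphas:
        scaled = rescale(crop, float(alpha), order=0) > 0.5
        coords = np.argwhere(scaled)
        if coords.size == 0:
            continue
        cy, cx = coords.mean(axis=0)
        for dy in range(-shift_radius, shift_radius + 1):
            for dx in range(-shift_radius, shift_radius + 1):
                sy = round(by + dy - cy)
                sx = round(bx + dx - cx)
                moved = {(y + sy, x + sx) for y, x in map(tuple, coords)}
                inter = len(moved & b)
                if inter:
                    iou = inter / (len(moved) + len(b) - inter)
                    best = max(best, iou)
    return best


def graph_partition(result: LinkResult) -> frozenset[frozenset]:
    """Connected components of the segment graph built from the pipeline's
    own fine matrices plus accepted skip pairs (networkx oracle)."""
    import networkx as nx

    g = nx.Graph()
    for segs in result.segments:
        for s in segs:
            g.add_node(s.key)
    for b in result.fine:
        for (p, q) in b.entries:
            g.add_edge((b.slice_index, p), (b.slice_index + 1, q))
    for (i, p, q, _r) in result.skip_pairs:
        g.add_edge((i, p), (i + 2, q))
    return frozenset(frozenset(c) for c in nx.connected_components(g))
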