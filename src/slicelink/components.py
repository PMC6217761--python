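"""Per-slice 2D segment extraction and bounding-box geometry.

Coordinate convention (used package-wide): stacks are indexed (z, y, x),
0-based; within a slice a pixel is (y, x) = (row, column).  Bounding boxes
are half-open ``[x0, x1) x [y0, y1)``.  Label 0 is background everywhere.

A *segment* is one 2D-connected foreground region on one slice — the unit
that gets grouped into 3D objects.  Extraction mirrors the classic
regionprops stage: connected components with their tight bounding boxes,
areas and centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = ["BoundingBox", "Segment2D", "bbox_iou", "extract_segments"]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndi.generate_binary_structure(2, 1)

# Offset applied before packing (y, x) into one int64 so that moderately
# negative transformed coordinates still encode to distinct keys.
_GUARD = 1 << 20


def encode_pixels(coords: np.ndarray) -> np.ndarray:
    """Pack (N, 2) integer (y, x) coordinates into sorted int64 keys."""
    c = np.asarray(coords, dtype=np.int64)
    if c.ndim != 2 or c.shape[1] != 2:
        raise ValueError("coords must have shape (N, 2)")
    return np.sort(((c[:, 0] + _GUARD) << 32) + (c[:, 1] + _GUARD))


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned half-open box ``[x0, x1) x [y0, y1)``."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate bounding box {self!r}")

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    @property
    def area(self) -> int:
        return self.width * self.height


def bbox_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two bounding boxes.

    Returns 0.0 for disjoint boxes; disjoint boxes imply disjoint segments,
    which is what makes the box IoU a sound (cheap) screening test before
    any pixel-level comparison.
    """
    iw = min(a.x1, b.x1) - max(a.x0, b.x0)
    ih = min(a.y1, b.y1) - max(a.y0, b.y0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (a.area + b.area - inter)


@dataclass
class Segment2D:
    """One connected 2D region on one slice.

    ``pixels`` is an (N, 2) int array of (y, x) coordinates in row-major
    order; ``pixel_keys`` is the same set packed into sorted int64 keys for
    fast set intersection.
    """

    slice_index: int
    segment_index: int
    pixels: np.ndarray
    bbox: BoundingBox
    area: int
    centroid: tuple[float, float]  # (y, x)
    _keys: np.ndarray | None = field(default=None, repr=False, compare=False)

    @classmethod
    def from_pixels(
        cls, coords: np.ndarray, slice_index: int, segment_index: int
    ) -> "Segment2D":
        coords = np.asarray(coords, dtype=np.int64)
        if coords.size == 0:
            raise ValueError("a segment must contain at least one pixel")
        ys, xs = coords[:, 0], coords[:, 1]
        bbox = BoundingBox(
            x0=int(xs.min()), y0=int(ys.min()), x1=int(xs.max()) + 1, y1=int(ys.max()) + 1
        )
        return cls(
            slice_index=slice_index,
            segment_index=segment_index,
            pixels=coords,
            bbox=bbox,
            area=int(coords.shape[0]),
            centroid=(float(ys.mean()), float(xs.mean())),
        )

    @property
    def key(self) -> tuple[int, int]:
        return (self.slice_index, self.segment_index)

    @property
    def pixel_keys(self) -> np.ndarray:
        if self._keys is None:
            self._keys = encode_pixels(self.pixels)
        return self._keys


def _components_of(mask: np.ndarray, connectivity: int) -> list[np.ndarray]:
    structure = _EIGHT if connectivity == 8 else _FOUR
    lab, n = ndi.label(mask, structure=structure)
    if n == 0:
        return []
    coords = np.argwhere(lab > 0)  # row-major order
    vals = lab[coords[:, 0], coords[:, 1]]
    order = np.argsort(vals, kind="stable")
    coords = coords[order]
    counts = np.bincount(vals, minlength=n + 1)[1:]
    return list(np.split(coords, np.cumsum(counts)[:-1]))


def extract_segments(
    mask: np.ndarray,
    slice_index: int = 0,
    *,
    connectivity: int = 8,
    min_size: int = 0,
) -> list[Segment2D]:
    """Extract 2D segments from a non-negative integer (or boolean) mask.

    Binary masks yield plain connected components.  Pre-labeled masks yield
    one segment per distinct nonzero value, each further split into
    connected components if a value's support is disconnected.  Segments
    are ordered by their first foreground pixel in row-major scan order, so
    downstream matrix indices are deterministic.

    Parameters
    ----------
    connectivity : 4 or 8
        In-plane pixel connectivity (default 8, standard for blob-like
        organelle masks).
    min_size : int
        Drop segments smaller than this many pixels (default 0: keep all).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {mask.shape}")
    if mask.dtype == bool:
        mask = mask.astype(np.uint8)
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError(f"mask must be integer-typed, got {mask.dtype}")
    if mask.size and int(mask.min()) < 0:
        raise ValueError("mask values must be non-negative")

    values = np.unique(mask)
    components: list[np.ndarray] = []
    for v in values:
        if v == 0:
            continue
        components.extend(_components_of(mask == v, connectivity))
    if min_size > 0:
        components = [c for c in components if c.shape[0] >= min_size]
    # Deterministic ordering: first pixel (row-major) of each component.
    components.sort(key=lambda c: (int(c[0, 0]), int(c[0, 1])))
    return [
        Segment2D.from_pixels(coords, slice_index, idx)
        for idx, coords in enumerate(components)
    ]
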