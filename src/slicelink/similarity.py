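"""Coarse and refined similarity between segments in different slices.

The coarse stage scores a candidate pair by bounding-box IoU and sorts it
into one of three cases against thresholds ``0 <= T_l <= T_h <= 1``:

* ``c in [T_h, 1]``   — CONNECT: accept without further work;
* ``c in [0, T_l)``   — NONE: reject, entry zeroed;
* ``c in [T_l, T_h)`` — VALIDATE: recompute from the pixel masks.

Validation combines a *position* term P (mask IoU in place — how much the
two cross-sections actually overlap) with a *shape* term S (best mask IoU
after scaling + translation of one segment — how alike the shapes are,
regardless of in-plane drift):

    c = (P^2 + lam * S^2) / (1 + lam),      lam >= 0.

``lam`` balances the two regimes: blob-like structures (mitochondria) have
large slice-to-slice overlap, so a small ``lam`` keeps the position term
dominant; thin sheet-like structures (synaptic clefts) drift and may not
overlap at all, so a larger ``lam`` lets shape agreement carry the link.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .components import Segment2D, encode_pixels

__all__ = [
    "ScreeningCase",
    "TransformSpec",
    "LinkParams",
    "classify_coarse",
    "position_term",
    "shape_term",
    "refined_similarity",
]


class ScreeningCase(enum.Enum):
    CONNECT = "connect"
    NONE = "none"
    VALIDATE = "validate"


@dataclass(frozen=True)
class TransformSpec:
    """The finite search set H of scale-then-translate transformations.

    Each member scales one segment about its centroid by ``alpha`` and then
    translates it.  Translations always include exact centroid alignment
    plus a +/- 1 px local refinement in each axis; the scale grid is a
    small geometric ladder, optionally augmented by the equivalent-diameter
    ratio of the two segments (so a uniformly grown/shrunk cross-section
    still scores ~1).  The identity transformation is always a member, so
    the shape term can never fall below the position term.
    """

    scales: tuple[float, ...] = (0.80, 0.90, 1.00, 1.11, 1.25)
    include_size_ratio: bool = True
    translation_radius: int = 1

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.scales):
            raise ValueError("scales must be positive")
        if self.translation_radius < 0:
            raise ValueError("translation_radius must be >= 0")

    def offsets(self) -> list[tuple[int, int]]:
        out = [(0, 0)]
        for r in range(1, self.translation_radius + 1):
            out += [(r, 0), (-r, 0), (0, r), (0, -r)]
        return out


@dataclass(frozen=True)
class LinkParams:
    """Thresholds and balance parameters of the linking pipeline.

    t_low / t_high — coarse screening thresholds T_l, T_h on box IoU;
    t_fine — threshold T_s on the refined similarity (strict ``>``);
    lam — position/shape balance (>= 0);
    transforms — the shape-term search set H;
    skip_enabled — bridge single missing slices (i <-> i+2).
    """

    t_low: float = 0.01
    t_high: float = 0.4
    t_fine: float = 0.03
    lam: float = 0.5
    transforms: TransformSpec = field(default_factory=TransformSpec)
    skip_enabled: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.t_low <= self.t_high <= 1.0):
            raise ValueError("need 0 <= t_low <= t_high <= 1")
        if not (0.0 <= self.t_fine < self.t_high or (self.t_fine == 0.0 == self.t_high)):
            raise ValueError("need t_fine in [0, t_high)")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")

    # -- presets -------------------------------------------------------
    @classmethod
    def mitochondria(cls, **kw) -> "LinkParams":
        """Blob-like preset: position term dominant (lam=0.5, T_s=0.03)."""
        return cls(**{"lam": 0.5, "t_fine": 0.03, **kw})

    @classmethod
    def synapse(cls, **kw) -> "LinkParams":
        """Sheet-like preset: shape term dominant (lam=2, T_s=0.03)."""
        return cls(**{"lam": 2.0, "t_fine": 0.03, **kw})

    @classmethod
    def connected_components(cls) -> "LinkParams":
        """Parameters under which linking degenerates to plain 3D
        connected components by pixel overlap: lam=0, T_s=0, T_l=0 and
        T_h=1 (so every candidate is pixel-validated), skip disabled."""
        return cls(t_low=0.0, t_high=1.0, t_fine=0.0, lam=0.0, skip_enabled=False)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "t_low": self.t_low,
            "t_high": self.t_high,
            "t_fine": self.t_fine,
            "lam": self.lam,
            "skip_enabled": self.skip_enabled,
            "transforms": {
                "scales": list(self.transforms.scales),
                "include_size_ratio": self.transforms.include_size_ratio,
                "translation_radius": self.transforms.translation_radius,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinkParams":
        d = dict(d)
        t = d.pop("transforms", None)
        transforms = TransformSpec(
            scales=tuple(t.get("scales", TransformSpec.scales)),
            include_size_ratio=t.get("include_size_ratio", True),
            translation_radius=t.get("translation_radius", 1),
        ) if t else TransformSpec()
        return cls(transforms=transforms, **d)

    @classmethod
    def from_file(cls, path: str | Path) -> "LinkParams":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def replace(self, **kw) -> "LinkParams":
        return replace(self, **kw)


def classify_coarse(c: float, params: LinkParams) -> ScreeningCase:
    """Sort a coarse (box-IoU) similarity into the three screening cases."""
    if not (0.0 <= c <= 1.0):
        raise ValueError(f"coarse similarity {c} outside [0, 1]")
    if c >= params.t_high:
        return ScreeningCase.CONNECT
    if c < params.t_low:
        return ScreeningCase.NONE
    return ScreeningCase.VALIDATE


def _intersection_size(keys_a: np.ndarray, keys_b: np.ndarray) -> int:
    return int(np.intersect1d(keys_a, keys_b, assume_unique=True).size)


def position_term(seg_a: Segment2D, seg_b: Segment2D) -> float:
    """Mask IoU of the two segments in place.

    Both pixel sets live in the common slice coordinate frame, so the IoU
    is independent of any crop domain that contains them both.
    """
    inter = _intersection_size(seg_a.pixel_keys, seg_b.pixel_keys)
    if inter == 0:
        return 0.0
    return inter / (seg_a.area + seg_b.area - inter)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # Fixed tie rule for determinism: .5 rounds away from zero.
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


def _scaled_pixels(seg: Segment2D, alpha: float) -> np.ndarray:
    """Rasterize the segment scaled by ``alpha`` about its centroid.

    Nearest-neighbour resampling by inverse mapping over the scaled
    bounding extent (no holes for alpha > 1, deduplicated for alpha < 1).
    """
    if alpha == 1.0:
        return seg.pixels
    y0, x0 = seg.bbox.y0, seg.bbox.x0
    h, w = seg.bbox.height, seg.bbox.width
    mask = np.zeros((h, w), dtype=bool)
    mask[seg.pixels[:, 0] - y0, seg.pixels[:, 1] - x0] = True
    cy, cx = seg.centroid
    # Output extent: image of the bbox corners under q = alpha*(p - c) + c.
    eps = 1e-9
    qy = np.arange(
        math.ceil(alpha * (y0 - cy) + cy - eps),
        math.floor(alpha * (y0 + h - 1 - cy) + cy + eps) + 1,
        dtype=np.int64,
    )
    qx = np.arange(
        math.ceil(alpha * (x0 - cx) + cx - eps),
        math.floor(alpha * (x0 + w - 1 - cx) + cx + eps) + 1,
        dtype=np.int64,
    )
    if qy.size == 0 or qx.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    py = _round_half_away((qy - cy) / alpha + cy) - y0
    px = _round_half_away((qx - cx) / alpha + cx) - x0
    ok_y = (py >= 0) & (py < h)
    ok_x = (px >= 0) & (px < w)
    qy, py = qy[ok_y], py[ok_y]
    qx, px = qx[ok_x], px[ok_x]
    hit = mask[np.ix_(py, px)]
    yy, xx = np.nonzero(hit)
    return np.column_stack([qy[yy], qx[xx]])


def shape_term(seg_a: Segment2D, seg_b: Segment2D, spec: TransformSpec) -> float:
    """Best in-place IoU of ``seg_a`` against ``seg_b`` over the transform
    set H (scaling about seg_a's centroid, then translation).  Bounded
    below by the position term because the identity is in H."""
    best = position_term(seg_a, seg_b)
    if best >= 1.0:
        return 1.0
    scales = list(spec.scales)
    if spec.include_size_ratio:
        scales.append(math.sqrt(seg_b.area / seg_a.area))
    offsets = spec.offsets()
    keys_b = seg_b.pixel_keys
    for alpha in scales:
        coords = _scaled_pixels(seg_a, alpha)
        if coords.shape[0] == 0:
            continue
        cy, cx = coords[:, 0].mean(), coords[:, 1].mean()
        for dy, dx in offsets:
            shift_y = int(_round_half_away(np.asarray(seg_b.centroid[0] + dy - cy)))
            shift_x = int(_round_half_away(np.asarray(seg_b.centroid[1] + dx - cx)))
            moved = coords + np.array([shift_y, shift_x], dtype=np.int64)
            keys_m = encode_pixels(moved)
            inter = _intersection_size(keys_m, keys_b)
            if inter == 0:
                continue
            iou = inter / (coords.shape[0] + seg_b.area - inter)
            if iou > best:
                best = iou
                if best >= 1.0:
                    return 1.0
    return min(best, 1.0)


def refined_similarity(seg_a: Segment2D, seg_b: Segment2D, params: LinkParams) -> float:
    """Validated similarity ``(P^2 + lam * S^2) / (1 + lam)``.

    At lam=0 this is the squared in-place overlap; as lam grows the shape
    term dominates.  The shape term is only computed when it can matter.
    """
    p = position_term(seg_a, seg_b)
    if params.lam == 0.0:
        return p * p
    s = shape_term(seg_a, seg_b, params.transforms)
    return (p * p + params.lam * s * s) / (1.0 + params.lam)
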