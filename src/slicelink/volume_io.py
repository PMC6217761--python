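"""Reading and writing slice stacks, label volumes and object tables.

Input stacks are either a directory of lexicographically ordered PNG/TIFF
files (one slice each) or a single multipage TIFF.  Masks may be binary
(foreground components are the segments) or pre-labeled (each distinct
nonzero value per slice is one segment); both dialects flow through the
same extraction.  Outputs are a multipage TIFF label volume (pixel value =
final 3D label, 0 = background) with a CSV + JSON sidecar of per-object
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .components import Segment2D, extract_segments
from .labels import LabelAssignment

__all__ = [
    "SliceStack",
    "read_stack",
    "write_labeled_stack",
    "build_object_table",
]

_SLICE_SUFFIXES = {".png", ".tif", ".tiff"}

OBJECT_COLUMNS = ["label", "n_segments", "voxel_count", "volume_nm3", "z_first", "z_last"]


@dataclass
class SliceStack:
    """An ordered stack of same-sized 2D integer masks.

    ``masks`` has shape (n_slices, H, W); ``voxel_size`` is the physical
    voxel extent (x_nm, y_nm, z_nm) — e.g. (2, 2, 50) for typical
    serial-section EM with 2 nm pixels and 50 nm sections.
    """

    masks: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 3:
            raise ValueError(f"masks must be (n, H, W), got shape {self.masks.shape}")
        if self.masks.shape[0] < 1:
            raise ValueError("a stack needs at least one slice")
        if self.masks.dtype == bool:
            self.masks = self.masks.astype(np.uint8)
        if not np.issubdtype(self.masks.dtype, np.integer):
            raise TypeError(f"masks must be integer-typed, got {self.masks.dtype}")
        if self.masks.size and int(self.masks.min()) < 0:
            raise ValueError("mask values must be non-negative")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive reals (x, y, z)")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def n_slices(self) -> int:
        return int(self.masks.shape[0])

    @property
    def height(self) -> int:
        return int(self.masks.shape[1])

    @property
    def width(self) -> int:
        return int(self.masks.shape[2])

    @property
    def voxel_volume_nm3(self) -> float:
        x, y, z = self.voxel_size
        return x * y * z


def _read_slice(path: Path) -> np.ndarray:
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            img = tifffile.imread(path)
        else:
            img = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 — re-raise naming the file
        raise OSError(f"failed to read slice image {path}: {exc}") from exc
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2D mask, got shape {img.shape}"
        )
    return img


def read_stack(
    path: str | Path, voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
) -> SliceStack:
    """Read a stack from a directory of slice images or a multipage TIFF.

    Directory entries are taken in lexicographic filename order; a single
    TIFF file is read page by page.  All slices must share one shape.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _SLICE_SUFFIXES
        )
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF slice images found in {path}")
        slices = [_read_slice(p) for p in files]
        shapes = {s.shape for s in slices}
        if len(shapes) > 1:
            raise ValueError(
                f"slice dimension mismatch in {path}: found shapes {sorted(shapes)}"
            )
        masks = np.stack(slices)
    elif path.is_file():
        try:
            masks = tifffile.imread(path)
        except Exception as exc:  # noqa: BLE001
            raise OSError(f"failed to read stack {path}: {exc}") from exc
        masks = np.asarray(masks)
        if masks.ndim == 2:
            masks = masks[None]
        if masks.ndim != 3:
            raise ValueError(f"{path}: expected 2D pages, got shape {masks.shape}")
    else:
        raise FileNotFoundError(f"no such file or directory: {path}")
    return SliceStack(masks=masks, voxel_size=voxel_size)


def _label_dtype(max_label: int) -> np.dtype:
    for dt in (np.uint8, np.uint16, np.uint32, np.uint64):
        if max_label <= np.iinfo(dt).max:
            return np.dtype(dt)
    raise ValueError(f"label {max_label} exceeds uint64 capacity")


def render_labels(
    stack: SliceStack,
    segments: list[list[Segment2D]],
    assignment: LabelAssignment,
) -> np.ndarray:
    """Rasterize final 3D labels into a volume (0 = background)."""
    finals = assignment.final_labels()
    max_label = max(finals.values(), default=0)
    vol = np.zeros(stack.masks.shape, dtype=_label_dtype(max_label))
    for segs in segments:
        for seg in segs:
            vol[seg.slice_index, seg.pixels[:, 0], seg.pixels[:, 1]] = finals[seg.key]
    return vol


def build_object_table(
    segments: list[list[Segment2D]],
    assignment: LabelAssignment,
    voxel_size: tuple[float, float, float],
) -> pd.DataFrame:
    """Per-object statistics: one row per final 3D label.

    ``volume_nm3`` is voxel_count x x_nm x y_nm x z_nm — a voxel-counting
    volume, appropriate for anisotropic stacks where each 2D pixel stands
    for a full section thickness.
    """
    vx = float(voxel_size[0]) * float(voxel_size[1]) * float(voxel_size[2])
    by_segment = {seg.key: seg for segs in segments for seg in segs}
    missing = [k for k in by_segment if k not in assignment]
    if missing:
        raise ValueError(f"assignment does not cover segments: {missing[:5]} ...")
    rows = []
    for label, members in sorted(assignment.groups().items()):
        voxels = sum(by_segment[k].area for k in members)
        zs = [k[0] for k in members]
        rows.append(
            {
                "label": label,
                "n_segments": len(members),
                "voxel_count": voxels,
                "volume_nm3": voxels * vx,
                "z_first": min(zs),
                "z_last": max(zs),
            }
        )
    return pd.DataFrame(rows, columns=OBJECT_COLUMNS)


def write_labeled_stack(
    stack: SliceStack,
    assignment: LabelAssignment,
    path: str | Path,
    segments: list[list[Segment2D]] | None = None,
) -> pd.DataFrame:
    """Write the labeled volume as a multipage TIFF plus CSV/JSON sidecars.

    Returns the object table.  ``segments`` may be passed to reuse an
    existing extraction; otherwise segments are re-extracted from the
    stack (deterministic, so labels land on the same regions).
    """
    path = Path(path)
    if segments is None:
        segments = [
            extract_segments(stack.masks[i], slice_index=i)
            for i in range(stack.n_slices)
        ]
    vol = render_labels(stack, segments, assignment)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, vol, photometric="minisblack")
    table = build_object_table(segments, assignment, stack.voxel_size)
    table.to_csv(path.with_suffix(".csv"), index=False)
    path.with_suffix(".json").write_text(
        json.dumps(table.to_dict(orient="records"), indent=2)
    )
    return table
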