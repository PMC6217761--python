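"""Synthetic slice stacks with known 3D ground truth.

The generator emulates the two data regimes the linking pipeline is built
for:

* ``blob`` — filled ellipses with smoothly varying axes and a small
  centroid random walk: mitochondria-like cross-sections with large
  slice-to-slice overlap (the position term carries the links).
* ``sheet`` — thin rotated rectangles whose consecutive cross-sections are
  exact integer-translated copies with deliberately small pixel overlap
  (an alternating "zigzag" translation of about half the sheet length
  along its axis plus half its thickness across): synaptic-cleft-like
  sections where only the shape term can carry the links.

Objects live in disjoint grid cells with generous margins, so distinct
objects never share bounding-box overlap — the generator's realization of
the sparsity these structures show in EM tissue.  Within an object the
generator can inject a split (one section branching into two disjoint
lobes), a merge (two lobes joining), and single-slice gaps (a section
missing on one slice), each recorded in the event log.

Everything is driven by one seeded NumPy generator: the same config
produces bit-identical stacks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

from .components import extract_segments
from .labels import LabelAssignment
from .volume_io import SliceStack

__all__ = ["ScenarioConfig", "SimEvent", "GenerationError", "generate"]

_BLOB_AY = (8.0, 11.0)  # semi-axis ranges, px
_BLOB_AX = (7.0, 9.0)
# Branch lobes are scaled-down copies tucked inside the parent footprint
# (offset ~half the parent's x semi-axis), so a lobe always shares
# bounding-box overlap with the parent section across the event while the
# two lobes stay disjoint.
_BLOB_CHILD_SCALE = 0.38
_SHEET_LEN = (30.0, 60.0)
_SHEET_THICK = (3.0, 6.0)
_SHEET_ALONG_FRAC = 0.55  # zigzag shift as fraction of sheet length


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimEvent:
    kind: str  # "split" | "merge" | "gap"
    object_id: int
    slice_index: int

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "object_id": self.object_id,
            "slice_index": self.slice_index,
        }


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic stack.

    ``p_split``/``p_merge`` are per-object probabilities of carrying one
    branching event; ``n_gaps`` single-slice dropouts are placed on
    distinct event-free objects; ``drift_px`` bounds the per-slice centroid
    jitter (blob family); ``scale_jitter`` bounds the per-slice relative
    size change (blob family — sheets are exact translated copies by
    construction).
    """

    n_slices: int = 12
    height: int = 256
    width: int = 256
    n_objects: int = 6
    shape_family: str = "blob"
    p_split: float = 0.0
    p_merge: float = 0.0
    n_gaps: int = 0
    drift_px: int = 2
    scale_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.height < 8 or self.width < 8:
            raise ValueError("n_slices must be >= 1 and frame at least 8x8")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if self.shape_family not in ("blob", "sheet"):
            raise ValueError("shape_family must be 'blob' or 'sheet'")
        if not (0 <= self.p_split <= 1 and 0 <= self.p_merge <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.p_split + self.p_merge > 1:
            raise ValueError("p_split + p_merge must not exceed 1")
        if self.n_gaps < 0 or self.drift_px < 0 or self.scale_jitter < 0:
            raise ValueError("n_gaps, drift_px and scale_jitter must be >= 0")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_slices": self.n_slices,
            "height": self.height,
            "width": self.width,
            "n_objects": self.n_objects,
            "shape_family": self.shape_family,
            "p_split": self.p_split,
            "p_merge": self.p_merge,
            "n_gaps": self.n_gaps,
            "drift_px": self.drift_px,
            "scale_jitter": self.scale_jitter,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})


def _round_int(x: np.ndarray | float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.trunc(x + np.copysign(0.5, x)).astype(np.int64)


def _cell_geometry(config: ScenarioConfig) -> tuple[int, int, int]:
    """(cell_h, cell_w, room): room = max deviation of an object's anchor
    from its cell centre; cells are sized so no trajectory can leave its
    cell or approach a neighbour."""
    sj = config.scale_jitter
    if config.shape_family == "blob":
        room = 2 * config.drift_px + 2
        half_y = math.ceil(_BLOB_AY[1] * (1 + sj)) + room + 2
        half_x = math.ceil(_BLOB_AX[1] * (1 + sj)) + room + 3
    else:
        room = 0  # sheets move only by their deterministic zigzag
        half_shape = math.ceil((_SHEET_LEN[1] + _SHEET_THICK[1]) / 2) + 1
        shift = math.ceil(_SHEET_ALONG_FRAC * _SHEET_LEN[1] + _SHEET_THICK[1])
        # branch halves start from the parent's shifted position and add
        # their own (half-length) zigzag on top
        half_shift = math.ceil(_SHEET_ALONG_FRAC * _SHEET_LEN[1] / 2 + _SHEET_THICK[1])
        half_y = half_x = half_shape + shift + half_shift + 2
    return 2 * half_y, 2 * half_x, room


@dataclass
class _Branch:
    """One chain of cross-sections of an object: a per-slice footprint."""

    slices: range
    # slice -> (N, 2) absolute (y, x) pixel coordinates
    footprint: dict[int, np.ndarray] = field(default_factory=dict)


def _blob_pixels(cy: float, cx: float, ay: float, ax: float, shape) -> np.ndarray:
    rr, cc = draw_ellipse(cy, cx, ay, ax, shape=shape)
    return np.column_stack([rr, cc]).astype(np.int64)


def _sheet_template(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Rasterize one rotated rectangle about the origin.

    Returns (offsets, axis unit vector u as (y, x), length, thickness).
    """
    length = rng.uniform(*_SHEET_LEN)
    thick = rng.uniform(*_SHEET_THICK)
    theta = rng.uniform(0.0, math.pi)
    u = np.array([math.sin(theta), math.cos(theta)])  # along the sheet
    nvec = np.array([math.cos(theta), -math.sin(theta)])  # across
    corners = np.array(
        [
            +0.5 * length * u + 0.5 * thick * nvec,
            +0.5 * length * u - 0.5 * thick * nvec,
            -0.5 * length * u - 0.5 * thick * nvec,
            -0.5 * length * u + 0.5 * thick * nvec,
        ]
    )
    guard = int(math.ceil(np.abs(corners).max())) + 2
    rr, cc = draw_polygon(corners[:, 0] + guard, corners[:, 1] + guard)
    offsets = np.column_stack([rr, cc]).astype(np.int64) - guard
    return offsets, u, length, thick


def _split_template(
    offsets: np.ndarray, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a sheet template into two halves with a >=3 px gap along its axis."""
    proj = offsets @ u
    lo = offsets[proj < -1.5]
    hi = offsets[proj > 1.5]
    if lo.shape[0] == 0 or hi.shape[0] == 0:
        raise GenerationError("sheet too short to split; increase sheet length")
    return lo, hi


def _object_branches(
    config: ScenarioConfig,
    rng: np.random.Generator,
    anchor: np.ndarray,
    room: int,
    z0: int,
    z1: int,
    event: tuple[str, int] | None,
) -> list[_Branch]:
    """Build the per-slice footprints of one object inside its cell."""
    if config.shape_family == "blob":
        return _blob_branches(config, rng, anchor, room, z0, z1, event)
    return _sheet_branches(config, rng, anchor, z0, z1, event)


def _blob_branches(config, rng, anchor, room, z0, z1, event) -> list[_Branch]:
    ay = rng.uniform(*_BLOB_AY)
    ax = rng.uniform(*_BLOB_AX)
    sj = config.scale_jitter
    off = round(0.5 * ax) + 1
    # Centroid random walk clamped to the cell's allowed box.
    centers = np.zeros((z1 + 1 - z0, 2), dtype=np.int64)
    pos = anchor.copy()
    for t in range(z0, z1 + 1):
        centers[t - z0] = pos
        step = rng.integers(-config.drift_px, config.drift_px + 1, size=2)
        pos = np.clip(pos + step, anchor - room, anchor + room)
    factors = 1.0 + rng.uniform(-sj, sj, size=z1 + 1 - z0)

    def section(t: int, scale: float, dx: int) -> np.ndarray:
        cy, cx = centers[t - z0]
        f = factors[t - z0] * scale
        return _blob_pixels(
            float(cy), float(cx + dx), ay * f, ax * f, (config.height, config.width)
        )

    kind, t_ev = event if event else (None, -1)
    branches: list[_Branch] = []
    if kind == "split":
        parent = _Branch(range(z0, t_ev))
        for t in parent.slices:
            parent.footprint[t] = section(t, 1.0, 0)
        lobe_a, lobe_b = _Branch(range(t_ev, z1 + 1)), _Branch(range(t_ev, z1 + 1))
        for t in lobe_a.slices:
            lobe_a.footprint[t] = section(t, _BLOB_CHILD_SCALE, -off)
            lobe_b.footprint[t] = section(t, _BLOB_CHILD_SCALE, +off)
        branches = [parent, lobe_a, lobe_b]
    elif kind == "merge":
        lobe_a, lobe_b = _Branch(range(z0, t_ev)), _Branch(range(z0, t_ev))
        for t in lobe_a.slices:
            lobe_a.footprint[t] = section(t, _BLOB_CHILD_SCALE, -off)
            lobe_b.footprint[t] = section(t, _BLOB_CHILD_SCALE, +off)
        whole = _Branch(range(t_ev, z1 + 1))
        for t in whole.slices:
            whole.footprint[t] = section(t, 1.0, 0)
        branches = [lobe_a, lobe_b, whole]
    else:
        whole = _Branch(range(z0, z1 + 1))
        for t in whole.slices:
            whole.footprint[t] = section(t, 1.0, 0)
        branches = [whole]
    return branches


def _sheet_branches(config, rng, anchor, z0, z1, event) -> list[_Branch]:
    offsets, u, length, thick = _sheet_template(rng)
    cross = math.ceil(thick / 2)
    nvec = np.array([u[1], -u[0]])
    delta = _round_int(_SHEET_ALONG_FRAC * length * u + cross * nvec)

    def positions(base: np.ndarray, slices: range, own_delta: np.ndarray) -> dict[int, np.ndarray]:
        return {t: base + ((t - slices.start) % 2) * own_delta for t in slices}

    kind, t_ev = event if event else (None, -1)
    branches: list[_Branch] = []
    if kind in ("split", "merge"):
        lo, hi = _split_template(offsets, u)
        half_delta = {
            id(lo): _round_int(_SHEET_ALONG_FRAC * (length / 2) * u + cross * nvec),
            id(hi): _round_int(_SHEET_ALONG_FRAC * (length / 2) * u + cross * nvec),
        }
        if kind == "split":
            whole_rng, halves_rng = range(z0, t_ev), range(t_ev, z1 + 1)
        else:
            halves_rng, whole_rng = range(z0, t_ev), range(t_ev, z1 + 1)
        whole = _Branch(whole_rng)
        pos_whole = positions(anchor, whole_rng, delta)
        for t in whole_rng:
            whole.footprint[t] = offsets + pos_whole[t]
        # Halves keep the parent's last (split) / first (merge) anchor so the
        # transition sections stay inside the whole footprint: direct connect.
        if kind == "split":
            edge_t = t_ev - 1
            base = pos_whole.get(edge_t, anchor)
        else:
            base = anchor
        halves = []
        for part in (lo, hi):
            br = _Branch(halves_rng)
            pos = positions(base, halves_rng, half_delta[id(part)])
            for t in halves_rng:
                br.footprint[t] = part + pos[t]
            halves.append(br)
        if kind == "merge":
            # The whole resumes from the halves' last position so that the
            # merge sections overlap both halves.
            last = positions(base, halves_rng, half_delta[id(lo)]).get(t_ev - 1, anchor)
            shift = last - pos_whole[t_ev]
            for t in whole_rng:
                whole.footprint[t] = whole.footprint[t] + shift
        branches = halves + [whole] if kind == "merge" else [whole] + halves
    else:
        br = _Branch(range(z0, z1 + 1))
        pos = positions(anchor, br.slices, delta)
        for t in br.slices:
            br.footprint[t] = offsets + pos[t]
        branches = [br]
    return branches


def generate(
    config: ScenarioConfig,
) -> tuple[SliceStack, LabelAssignment, list[SimEvent]]:
    """Generate a stack, its ground-truth grouping, and the event log.

    Returns ``(stack, truth, events)``: a binary-mask :class:`SliceStack`,
    a :class:`LabelAssignment` giving every extracted 2D segment its true
    3D object, and the injected split/merge/gap events.
    """
    rng = np.random.default_rng(config.seed)
    cell_h, cell_w, room = _cell_geometry(config)
    rows, cols = config.height // cell_h, config.width // cell_w
    capacity = rows * cols
    if config.n_objects > capacity:
        raise GenerationError(
            f"{config.n_objects} objects do not fit: frame "
            f"{config.height}x{config.width} holds at most {capacity} "
            f"{config.shape_family} cells — reduce n_objects or enlarge the frame"
        )
    cells = rng.permutation(capacity)[: config.n_objects]

    n = config.n_slices
    # Gap carriers are reserved first (one gap per object, kept free of
    # split/merge events so each gap breaks exactly one chain), then the
    # remaining objects draw their branching events.
    if config.n_gaps > 0 and n < 3:
        raise GenerationError("gaps need at least 3 slices")
    if config.n_gaps > config.n_objects:
        raise GenerationError(
            f"cannot place {config.n_gaps} gaps on {config.n_objects} objects "
            "— raise n_objects"
        )
    gap_objects = sorted(
        rng.choice(config.n_objects, size=config.n_gaps, replace=False).tolist()
    ) if config.n_gaps else []
    kinds: list[str | None] = []
    for obj in range(config.n_objects):
        u = rng.random()
        if obj in gap_objects or n < 5:
            kinds.append(None)
        elif u < config.p_split:
            kinds.append("split")
        elif u < config.p_split + config.p_merge:
            kinds.append("merge")
        else:
            kinds.append(None)

    vol = np.zeros((n, config.height, config.width), dtype=np.uint16)
    events: list[SimEvent] = []
    for obj in range(config.n_objects):
        cell = int(cells[obj])
        r, c = divmod(cell, cols)
        anchor = np.array([r * cell_h + cell_h // 2, c * cell_w + cell_w // 2])
        # Span: event and gap carriers keep the full stack; others may
        # start late / end early to exercise genuine starts and ends.
        z0, z1 = 0, n - 1
        if kinds[obj] is None and obj not in gap_objects and n >= 8 and rng.random() < 0.35:
            if rng.random() < 0.5:
                z0 = int(rng.integers(1, n // 3 + 1))
            else:
                z1 = n - 1 - int(rng.integers(1, n // 3 + 1))
        event = None
        if kinds[obj] is not None and z1 - z0 >= 3:
            t_ev = int(rng.integers(z0 + 2, z1 + 1))
            event = (kinds[obj], t_ev)
            events.append(SimEvent(kinds[obj], obj, t_ev))
        branches = _object_branches(config, rng, anchor, room, z0, z1, event)
        if obj in gap_objects:
            t_gap = int(rng.integers(z0 + 1, z1))
            events.append(SimEvent("gap", obj, t_gap))
        else:
            t_gap = -1
        for br in branches:
            for t, coords in br.footprint.items():
                if t == t_gap:
                    continue
                if (
                    coords[:, 0].min() < 0
                    or coords[:, 1].min() < 0
                    or coords[:, 0].max() >= config.height
                    or coords[:, 1].max() >= config.width
                ):
                    raise GenerationError(
                        f"object {obj} left the frame on slice {t} — "
                        "reduce n_objects or enlarge the frame"
                    )
                vol[t, coords[:, 0], coords[:, 1]] = obj + 1

    stack = SliceStack(masks=(vol > 0).astype(np.uint8))
    truth = LabelAssignment()
    for i in range(n):
        for seg in extract_segments(stack.masks[i], slice_index=i):
            truth.assign(seg.key, int(vol[i, seg.pixels[0, 0], seg.pixels[0, 1]]))
    return stack, truth, events


def labeled_volume(config: ScenarioConfig) -> np.ndarray:
    """The ground-truth object-id volume for ``config`` (0 = background)."""
    stack, truth, _ = generate(config)
    from .volume_io import render_labels  # deferred: avoids cycle at import

    segments = [
        extract_segments(stack.masks[i], slice_index=i) for i in range(stack.n_slices)
    ]
    return render_labels(stack, segments, truth)
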