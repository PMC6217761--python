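"""Partition of 2D segments into 3D objects.

A :class:`LabelAssignment` is a disjoint-set over segment keys
``(slice_index, segment_index)``.  Seeds carry integer labels; merging two
groups keeps the *minimum* label as representative, so the final label of
every segment is the smallest seed label in its group — the deterministic
closure of pairwise "reassign min(j1, j2)" updates.
"""

from __future__ import annotations

from typing import Iterable, Mapping

__all__ = ["LabelAssignment"]

SegmentKey = tuple[int, int]


class LabelAssignment:
    def __init__(self) -> None:
        self._label: dict[SegmentKey, int] = {}
        self._parent: dict[int, int] = {}

    # -- construction --------------------------------------------------
    @classmethod
    def from_labels(cls, mapping: Mapping[SegmentKey, int]) -> "LabelAssignment":
        out = cls()
        for key, lab in mapping.items():
            out.assign(key, int(lab))
        return out

    def assign(self, key: SegmentKey, label: int) -> None:
        """Give ``key`` the (seed) label ``label``."""
        self._label[key] = label
        self._parent.setdefault(label, label)

    def merge_labels(self, j1: int, j2: int) -> None:
        """Union the groups carrying labels j1 and j2 (min label wins)."""
        r1, r2 = self._find(j1), self._find(j2)
        if r1 == r2:
            return
        if r1 < r2:
            self._parent[r2] = r1
        else:
            self._parent[r1] = r2

    def merge(self, key1: SegmentKey, key2: SegmentKey) -> None:
        self.merge_labels(self._label[key1], self._label[key2])

    def _find(self, j: int) -> int:
        root = j
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[j] != root:  # path compression
            self._parent[j], j = root, self._parent[j]
        return root

    # -- queries -------------------------------------------------------
    def __len__(self) -> int:
        return len(self._label)

    def __contains__(self, key: SegmentKey) -> bool:
        return key in self._label

    def keys(self) -> Iterable[SegmentKey]:
        return self._label.keys()

    def final_label(self, key: SegmentKey) -> int:
        return self._find(self._label[key])

    def final_labels(self) -> dict[SegmentKey, int]:
        return {key: self._find(lab) for key, lab in self._label.items()}

    def groups(self) -> dict[int, list[SegmentKey]]:
        """Final label -> sorted list of member segment keys."""
        out: dict[int, list[SegmentKey]] = {}
        for key, lab in self._label.items():
            out.setdefault(self._find(lab), []).append(key)
        for members in out.values():
            members.sort()
        return out

    @property
    def n_objects(self) -> int:
        return len({self._find(lab) for lab in self._label.values()})

    def partition(self) -> frozenset[frozenset[SegmentKey]]:
        """Label-free view for comparisons up to relabeling."""
        return frozenset(frozenset(m) for m in self.groups().values())

    def same_partition(self, other: "LabelAssignment") -> bool:
        return self.partition() == other.partition()

    def copy(self) -> "LabelAssignment":
        out = LabelAssignment()
        out._label = dict(self._label)
        out._parent = dict(self._parent)
        return out
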