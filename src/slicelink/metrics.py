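"""Split/merge error counts of a predicted grouping against ground truth.

A *split error* is a true 3D object fragmented across several predicted
objects; a *merge error* is several true objects fused into one predicted
object.  Both are counted as excess pieces: a true object covered by k
predicted groups contributes k-1 split errors (and dually for merges), so
totals are additive over objects and the two counts swap under exchanging
the roles of prediction and truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .labels import LabelAssignment

__all__ = ["ErrorReport", "split_merge_errors"]


@dataclass(frozen=True)
class ErrorReport:
    split_errors: int
    merge_errors: int

    @property
    def total(self) -> int:
        return self.split_errors + self.merge_errors

    def to_dict(self) -> dict:
        return {
            "split_errors": self.split_errors,
            "merge_errors": self.merge_errors,
            "total": self.total,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        return (
            f"split={self.split_errors} merge={self.merge_errors} total={self.total}"
        )


def split_merge_errors(pred: LabelAssignment, truth: LabelAssignment) -> ErrorReport:
    """Count split and merge errors of ``pred`` against ``truth``.

    Both assignments must cover the identical set of 2D segments.
    """
    pred_labels = pred.final_labels()
    truth_labels = truth.final_labels()
    if pred_labels.keys() != truth_labels.keys():
        raise ValueError("prediction and truth cover different segment sets")
    pairs = {(truth_labels[k], pred_labels[k]) for k in truth_labels}
    split = len(pairs) - len({t for t, _ in pairs})
    merge = len(pairs) - len({p for _, p in pairs})
    return ErrorReport(split_errors=split, merge_errors=merge)
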