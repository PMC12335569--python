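"""Multi-class classification metrics for pattern/territory scoring.

Metrics are computed from a confusion matrix with rows = true class and
columns = predicted class:

* per-class F1: ``F1_c = 2 TP_c / (2 TP_c + FP_c + FN_c)``; a class that is
  never true and never predicted has no defined F1 and is reported as
  ``None``, never silently 0 — small-N classes must stay visible.
* balanced accuracy: the macro-average of per-class recall
  ``TP_c / (TP_c + FN_c)``; a class with zero true instances makes it
  undefined and raises.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix", "per_class_f1", "balanced_accuracy"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """C x C count table; rows index the true class, columns the predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        c = len(self.classes)
        if c < 2:
            raise ValueError("need at least 2 classes")
        if counts.shape != (c, c):
            raise ValueError(f"counts must be {c}x{c}, got {counts.shape}")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "classes", tuple(self.classes))
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(cls, y_true: Sequence, y_pred: Sequence,
                    classes: Sequence[str]) -> "ConfusionMatrix":
        idx = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
        for t, p in zip(y_true, y_pred, strict=True):
            counts[idx[t], idx[p]] += 1
        return cls(tuple(classes), counts)

    def tp(self, c: int) -> int:
        return int(self.counts[c, c])

    def fn(self, c: int) -> int:
        return int(self.counts[c].sum() - self.counts[c, c])

    def fp(self, c: int) -> int:
        return int(self.counts[:, c].sum() - self.counts[c, c])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index_label="true\\pred")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise ValueError("confusion matrix CSV must have identical row/column class names "
                             "(rows = true class)")
        return cls(tuple(df.columns), df.to_numpy())


def per_class_f1(cm: ConfusionMatrix) -> dict[str, float | None]:
    """Per-class F1 from the confusion matrix; degenerate classes map to None."""
    if cm.counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    out: dict[str, float | None] = {}
    for i, name in enumerate(cm.classes):
        tp, fp, fn = cm.tp(i), cm.fp(i), cm.fn(i)
        if tp + fp + fn == 0:
            out[name] = None
        else:
            out[name] = 2.0 * tp / (2.0 * tp + fp + fn)
    return out


def balanced_accuracy(cm: ConfusionMatrix) -> float:
    """Macro-averaged recall over classes."""
    if cm.counts.sum() == 0:
        raise ValueError("empty confusion matrix")
    recalls = []
    for i, name in enumerate(cm.classes):
        support = cm.tp(i) + cm.fn(i)
        if support == 0:
            raise ValueError(f"class {name!r} has zero true instances; balanced accuracy undefined")
        recalls.append(cm.tp(i) / support)
    return float(np.mean(recalls))
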