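"""Per-voxel majority-vote fusion of candidate segmentations.

The consensus rule: a voxel is lesion in the fused mask iff at least
``min_votes`` of the ``n_inputs`` candidate masks call it lesion. The
default 2-of-3 reproduces the consensus-of-at-least-two rule used to fuse
the top challenge submissions into a single ensemble segmentation; for
other n the default is the strict majority ``ceil((n+1)/2)``.

Voting is strictly on binary labels — probability maps must be binarized
first (:func:`strokekit.volumes_io.binarize`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from strokekit.seg_metrics import CaseMetrics, false_positive_volume_ml
from strokekit.volumes_io import LesionMask, check_compatible

__all__ = ["EnsembleSpec", "majority_vote", "ensemble_gain_report"]


def _default_min_votes(n: int) -> int:
    # strict majority; reproduces 2-of-3
    return math.ceil((n + 1) / 2)


@dataclass(frozen=True)
class EnsembleSpec:
    """Vote-fusion parameters: number of inputs and required agreement."""

    n_inputs: int = 3
    min_votes: int | None = None

    def __post_init__(self) -> None:
        if self.n_inputs < 1:
            raise ValueError("n_inputs must be >= 1")
        mv = self.min_votes if self.min_votes is not None else _default_min_votes(self.n_inputs)
        if not 1 <= mv <= self.n_inputs:
            raise ValueError(f"min_votes must be in [1, {self.n_inputs}], got {mv}")
        object.__setattr__(self, "min_votes", mv)


def majority_vote(masks: Sequence[LesionMask], spec: EnsembleSpec | None = None) -> LesionMask:
    """Fuse candidate masks: output voxel is 1 iff >= min_votes inputs are 1.

    Geometry is copied from the inputs, which must share shape and spacing.
    """
    if len(masks) == 0:
        raise ValueError("majority_vote requires at least one input mask")
    if spec is None:
        spec = EnsembleSpec(n_inputs=len(masks))
    if len(masks) != spec.n_inputs:
        raise ValueError(f"expected {spec.n_inputs} masks per spec, got {len(masks)}")
    ref = masks[0]
    for m in masks[1:]:
        check_compatible(ref, m)
    votes = np.zeros(ref.geometry.shape, dtype=np.int64)
    for m in masks:
        votes += m.voxels
    fused = (votes >= spec.min_votes).astype(np.uint8)
    return LesionMask(geometry=ref.geometry, voxels=fused)


def ensemble_gain_report(
    individual_metrics: dict[str, dict[str, CaseMetrics]],
    fused_metrics: dict[str, CaseMetrics],
    fp_volumes_ml: dict[str, dict[str, float]] | None = None,
) -> pd.DataFrame:
    """Summarize each input segmenter against the fused result.

    Parameters
    ----------
    individual_metrics
        ``{input_name: {case_id: CaseMetrics}}`` for each candidate segmenter.
    fused_metrics
        ``{case_id: CaseMetrics}`` for the vote-fused masks; case ids must
        match every input's.
    fp_volumes_ml
        Optional ``{input_name_or_'fused': {case_id: fp volume (ml)}}``; the
        false-positive volume of a prediction is the volume of predicted
        voxels outside the ground truth (:func:`false_positive_volume_ml`).

    Returns a table with one row per input plus one ``fused`` row, holding
    median and IQR of each metric and, when provided, mean FP volume.
    """
    fused_ids = set(fused_metrics)
    for name, cases in individual_metrics.items():
        if set(cases) != fused_ids:
            raise ValueError(f"case ids of input {name!r} do not match the fused set")

    def summarize(name: str, cases: dict[str, CaseMetrics]) -> dict:
        row: dict[str, float | str] = {"input": name}
        ids = sorted(cases)
        for metric in ("dsc", "lesion_f1", "avd_ml", "ald"):
            vals = np.array([getattr(cases[c], metric) for c in ids], dtype=float)
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            row[f"{metric}_median"] = med
            row[f"{metric}_iqr"] = q3 - q1
        if fp_volumes_ml is not None and name in fp_volumes_ml:
            row["mean_fp_volume_ml"] = float(np.mean([fp_volumes_ml[name][c] for c in ids]))
        return row

    rows = [summarize(name, cases) for name, cases in individual_metrics.items()]
    rows.append(summarize("fused", fused_metrics))
    return pd.DataFrame(rows)
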