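"""The four-metric evaluation suite for one prediction/ground-truth mask pair.

Metrics follow the stroke segmentation challenge convention:

* **DSC** — Dice similarity coefficient, ``2|P∩G| / (|P|+|G|)`` over voxels.
* **AVD** — absolute volume difference ``|vol(P) − vol(G)|`` in ml.
* **ALD** — absolute lesion count difference ``|K_P − K_G|`` over connected
  components.
* **lesion-wise F1** — detection F1 over lesion instances: a ground-truth
  lesion is a true positive when at least one predicted voxel overlaps it;
  a predicted lesion overlapping no ground-truth voxel is a false positive.

Empty-vs-empty convention: Dice and F1 are 1.0 (a correct "no ischemia"
prediction is perfect agreement); empty-vs-nonempty yields 0.0.

Lesion matching is by any-voxel overlap with no IoU threshold and no
one-to-one assignment: one predicted blob covering two ground-truth lesions
counts two true positives and no false positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from strokekit.instances import DEFAULT_CONNECTIVITY, label_components
from strokekit.volumes_io import LesionMask, check_compatible, mask_volume_ml

__all__ = [
    "CaseMetrics",
    "dice",
    "avd",
    "ald",
    "lesionwise_f1",
    "evaluate_case",
    "stratify_by_size",
    "false_positive_volume_ml",
    "SIZE_BIN_EDGES_ML",
]

#: Lesion-size bin edges in ml: [0,5), [5,20), [20,inf).
SIZE_BIN_EDGES_ML = (5.0, 20.0)
SIZE_BIN_LABELS = ("<5 ml", "5-20 ml", ">=20 ml")


@dataclass(frozen=True)
class CaseMetrics:
    """The four metrics for one prediction/ground-truth pair."""

    dsc: float
    lesion_f1: float
    avd_ml: float
    ald: int
    tp_lesions: int
    fp_lesions: int
    fn_lesions: int
    connectivity_used: int = DEFAULT_CONNECTIVITY

    def as_dict(self) -> dict[str, float]:
        return {
            "dsc": self.dsc,
            "lesion_f1": self.lesion_f1,
            "avd_ml": self.avd_ml,
            "ald": self.ald,
            "tp": self.tp_lesions,
            "fp": self.fp_lesions,
            "fn": self.fn_lesions,
            "connectivity": self.connectivity_used,
        }


def dice(pred: LesionMask, gt: LesionMask) -> float:
    """Voxel-overlap Dice score; 1.0 when both masks are empty."""
    check_compatible(pred, gt)
    p, g = pred.voxels.astype(bool), gt.voxels.astype(bool)
    denom = int(p.sum()) + int(g.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / denom


def avd(pred: LesionMask, gt: LesionMask) -> float:
    """Absolute volume difference in ml."""
    check_compatible(pred, gt)
    return abs(mask_volume_ml(pred) - mask_volume_ml(gt))


def ald(pred: LesionMask, gt: LesionMask, connectivity: int = DEFAULT_CONNECTIVITY) -> int:
    """Absolute difference in lesion counts under the given connectivity."""
    check_compatible(pred, gt)
    kp = label_components(pred, connectivity).n_instances
    kg = label_components(gt, connectivity).n_instances
    return abs(kp - kg)


def lesionwise_f1(
    pred: LesionMask, gt: LesionMask, connectivity: int = DEFAULT_CONNECTIVITY
) -> tuple[float, int, int, int]:
    """Lesion-instance detection F1 with any-voxel-overlap matching.

    Returns ``(f1, tp, fp, fn)`` where TP counts ground-truth instances
    touched by the prediction, FN those untouched, and FP predicted
    instances touching no ground-truth voxel. Both masks empty yields
    ``(1.0, 0, 0, 0)``.
    """
    check_compatible(pred, gt)
    lab_p = label_components(pred, connectivity)
    lab_g = label_components(gt, connectivity)

    pv = pred.voxels.astype(bool)
    gv = gt.voxels.astype(bool)

    gt_hit = np.unique(lab_g.labels[pv])
    tp = int((gt_hit > 0).sum())
    fn = lab_g.n_instances - tp
    pred_hit = np.unique(lab_p.labels[gv])
    fp = lab_p.n_instances - int((pred_hit > 0).sum())

    if tp + fp + fn == 0:
        return 1.0, 0, 0, 0
    return 2.0 * tp / (2.0 * tp + fp + fn), tp, fp, fn


def false_positive_volume_ml(pred: LesionMask, gt: LesionMask) -> float:
    """Volume of predicted voxels outside the ground truth, in ml."""
    check_compatible(pred, gt)
    n = int((pred.voxels.astype(bool) & ~gt.voxels.astype(bool)).sum())
    return n * pred.geometry.voxel_volume_ml


def evaluate_case(
    pred: LesionMask, gt: LesionMask, connectivity: int = DEFAULT_CONNECTIVITY
) -> CaseMetrics:
    """Compute all four metrics for one prediction/ground-truth pair."""
    f1, tp, fp, fn = lesionwise_f1(pred, gt, connectivity)
    return CaseMetrics(
        dsc=dice(pred, gt),
        lesion_f1=f1,
        avd_ml=avd(pred, gt),
        ald=ald(pred, gt, connectivity),
        tp_lesions=tp,
        fp_lesions=fp,
        fn_lesions=fn,
        connectivity_used=connectivity,
    )


def _size_bin(volume_ml: float) -> str:
    lo, hi = SIZE_BIN_EDGES_ML
    if volume_ml < lo:
        return SIZE_BIN_LABELS[0]
    if volume_ml < hi:
        return SIZE_BIN_LABELS[1]
    return SIZE_BIN_LABELS[2]


def stratify_by_size(cases: list[tuple[CaseMetrics, float]]) -> pd.DataFrame:
    """Summarize metrics per ground-truth lesion-size bin.

    Bins are ``[0,5)``, ``[5,20)``, ``[20,inf)`` ml (the 5 and 20 ml
    boundaries belong to the upper bin). Returns a table with per-bin case
    count and median / IQR of each metric.
    """
    if not cases:
        raise ValueError("stratify_by_size requires a non-empty case list")
    rows = []
    for cm, gt_vol in cases:
        rows.append({"size_bin": _size_bin(gt_vol), "gt_volume_ml": gt_vol, **cm.as_dict()})
    df = pd.DataFrame(rows)

    out = []
    for label in SIZE_BIN_LABELS:
        sub = df[df["size_bin"] == label]
        row: dict[str, float | int | str] = {"size_bin": label, "n_cases": len(sub)}
        for metric in ("dsc", "lesion_f1", "avd_ml", "ald"):
            if len(sub):
                q1, med, q3 = np.percentile(sub[metric], [25, 50, 75])
                row[f"{metric}_median"] = med
                row[f"{metric}_iqr"] = q3 - q1
            else:
                row[f"{metric}_median"] = np.nan
                row[f"{metric}_iqr"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def cases_to_frame(case_ids: list[str], metrics: list[CaseMetrics],
                   gt_volumes_ml: list[float] | None = None) -> pd.DataFrame:
    """Per-case metric table (one row per case) for CSV export."""
    rows = []
    for i, (cid, cm) in enumerate(zip(case_ids, metrics)):
        row = {"case_id": cid, **cm.as_dict()}
        if gt_volumes_ml is not None:
            row["gt_volume_ml"] = gt_volumes_ml[i]
        rows.append(row)
    return pd.DataFrame(rows)
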