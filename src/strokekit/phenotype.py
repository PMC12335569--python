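"""Rule-based clinical read-outs from a lesion mask.

Two heuristics defined by neuroradiologists are implemented:

**Stroke pattern** — a decision list over the mask's connected components,
applied in order:

1. total lesion volume 0 ml -> *no ischemia*;
2. largest lesion > 95% of total volume -> *single vessel infarct* (SVI);
3. at least three lesions AND (largest lesion < 60% of total volume OR
   total volume < 5 ml) -> *scattered infarcts* (embolic showers /
   micro-occlusions);
4. all remaining masks -> *SVI with accompanying scattered infarcts*.

Inequalities are strict exactly as stated: a largest-lesion fraction of
exactly 0.95 is not SVI; a total of exactly 5.0 ml fails the "< 5 ml"
clause; K = 3 satisfies ">= three". Rule 2 pre-empts rule 3, so a
dominant lesion with three tiny satellites is SVI.

**Vascular territory** — the lesion load (ml) is accumulated per territory
of an integer-labeled atlas in the mask's grid, and the scan is assigned
the territory with the largest load (argmax). Ties break by a fixed
territory ordering (MCA, PCA, ACA, pons/medulla, cerebellum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from strokekit.class_metrics import ConfusionMatrix
from strokekit.instances import DEFAULT_CONNECTIVITY, label_components, largest_instance_fraction
from strokekit.volumes_io import GridGeometry, LesionMask

__all__ = [
    "PatternRuleConfig",
    "PatternLabel",
    "TerritoryAtlas",
    "classify_pattern",
    "territory_loads",
    "dominant_territory",
    "phenotype_agreement",
    "TERRITORY_TIEBREAK_ORDER",
]

#: Fixed tie-break ordering for dominant-territory assignment.
TERRITORY_TIEBREAK_ORDER = ("MCA", "PCA", "ACA", "pons/medulla", "cerebellum")


class PatternLabel(str, Enum):
    """The four stroke-pattern sub-groups."""

    no_ischemia = "no_ischemia"
    svi = "svi"
    scattered = "scattered"
    svi_with_scattered = "svi_with_scattered"


@dataclass(frozen=True)
class PatternRuleConfig:
    """Thresholds of the stroke-pattern decision list.

    svi_fraction
        Largest-lesion volume fraction above which a scan is SVI (default
        0.95, i.e. ">95% of the total lesion volume").
    scattered_min_lesions
        Minimum lesion count for the scattered rule (default 3, inclusive).
    scattered_fraction
        Largest-lesion fraction below which the scattered clause holds
        (default 0.60, strict).
    scattered_total_ml
        Total-volume threshold below which the scattered clause holds
        (default 5.0 ml, strict).
    """

    svi_fraction: float = 0.95
    scattered_min_lesions: int = 3
    scattered_fraction: float = 0.60
    scattered_total_ml: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.scattered_fraction < self.svi_fraction < 1):
            raise ValueError("require 0 < scattered_fraction < svi_fraction < 1")
        if self.scattered_min_lesions < 2:
            raise ValueError("scattered_min_lesions must be >= 2")
        if self.scattered_total_ml <= 0:
            raise ValueError("scattered_total_ml must be > 0")


@dataclass(frozen=True)
class TerritoryAtlas:
    """Integer-labeled vascular-territory volume in the mask's grid.

    Label 0 means outside the atlas; every nonzero label must be named.
    """

    geometry: GridGeometry
    labels: np.ndarray = field(repr=False)
    names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.shape != self.geometry.shape:
            raise ValueError("atlas label array shape does not match geometry")
        if (labels < 0).any():
            raise ValueError("atlas labels must be non-negative")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"atlas labels without names: {sorted(missing)}")
        object.__setattr__(self, "labels", labels.astype(np.int32))
        object.__setattr__(self, "names", dict(self.names))


def classify_pattern(
    mask: LesionMask,
    rules: PatternRuleConfig | None = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> PatternLabel:
    """Assign a mask to one of the four stroke-pattern sub-groups.

    A total function: every mask receives exactly one label.
    """
    rules = rules or PatternRuleConfig()
    labeling = label_components(mask, connectivity)
    k = labeling.n_instances
    if k == 0:
        return PatternLabel.no_ischemia
    frac = largest_instance_fraction(labeling)
    total_ml = labeling.total_volume_ml
    if frac > rules.svi_fraction:
        return PatternLabel.svi
    if k >= rules.scattered_min_lesions and (
        frac < rules.scattered_fraction or total_ml < rules.scattered_total_ml
    ):
        return PatternLabel.scattered
    return PatternLabel.svi_with_scattered


def territory_loads(mask: LesionMask, atlas: TerritoryAtlas) -> dict[str, float]:
    """Lesion load (ml) per vascular territory.

    The returned mapping has one entry per named territory plus
    ``"out_of_atlas"`` for lesion voxels with atlas label 0; the loads
    partition the mask, so they sum to its total volume.
    """
    if mask.geometry.shape != atlas.geometry.shape:
        raise ValueError(
            f"mask shape {mask.geometry.shape} != atlas shape {atlas.geometry.shape}"
        )
    vox_ml = mask.geometry.voxel_volume_ml
    lesion_labels = atlas.labels[mask.voxels.astype(bool)]
    counts = np.bincount(lesion_labels, minlength=max(atlas.names, default=0) + 1)
    loads = {name: float(counts[lab]) * vox_ml if lab < len(counts) else 0.0
             for lab, name in atlas.names.items()}
    loads["out_of_atlas"] = float(counts[0]) * vox_ml if len(counts) else 0.0
    return loads


def dominant_territory(
    loads: Mapping[str, float],
    tiebreak_order: Sequence[str] = TERRITORY_TIEBREAK_ORDER,
) -> str | None:
    """Territory with the largest lesion load; None when all loads are 0.

    ``out_of_atlas`` load never wins. Exact ties break by ``tiebreak_order``
    (territories not in the order come after it, alphabetically).
    """
    candidates = {k: v for k, v in loads.items() if k != "out_of_atlas"}
    if not candidates or max(candidates.values()) <= 0:
        return None
    order = {name: i for i, name in enumerate(tiebreak_order)}

    def key(item: tuple[str, float]):
        name, load = item
        return (-load, order.get(name, len(order)), name)

    return min(candidates.items(), key=key)[0]


def phenotype_agreement(
    pred_masks: Mapping[str, LesionMask],
    gt_masks: Mapping[str, LesionMask],
    atlas: TerritoryAtlas,
    rules: PatternRuleConfig | None = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Confusion matrices of pattern and territory prediction over paired cases.

    Both read-outs are derived from the predicted and ground-truth masks of
    each case; rows of the matrices index the ground-truth-derived label.
    Cases whose ground truth has no dominant territory (empty mask) are
    excluded from the territory matrix.
    """
    if set(pred_masks) != set(gt_masks):
        raise ValueError("prediction and ground-truth case ids do not match")
    ids = sorted(gt_masks)

    pat_true = [classify_pattern(gt_masks[c], rules, connectivity).value for c in ids]
    pat_pred = [classify_pattern(pred_masks[c], rules, connectivity).value for c in ids]
    pattern_classes = [p.value for p in PatternLabel]
    pattern_cm = ConfusionMatrix.from_labels(pat_true, pat_pred, pattern_classes)

    terr_true, terr_pred = [], []
    for c in ids:
        t = dominant_territory(territory_loads(gt_masks[c], atlas))
        if t is None:
            continue
        p = dominant_territory(territory_loads(pred_masks[c], atlas))
        terr_true.append(t)
        terr_pred.append(p if p is not None else "none")
    terr_classes = [n for n in TERRITORY_TIEBREAK_ORDER if n in set(atlas.names.values())]
    terr_classes += sorted(set(atlas.names.values()) - set(terr_classes))
    if "none" in set(terr_pred):
        terr_classes.append("none")
    territory_cm = ConfusionMatrix.from_labels(terr_true, terr_pred, terr_classes)
    return pattern_cm, territory_cm
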