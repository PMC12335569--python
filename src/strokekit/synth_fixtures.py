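"""Deterministic synthetic lesion phantoms, corrupted segmentations, toy atlases.

These generators emulate the statistical structure of an ischemic-stroke
cohort — per-scan lesion counts, log-normal-ish lesion volumes spanning
under 5 ml to over 20 ml, single-vessel versus scattered configurations —
using simple rasterized ellipsoids on a binary grid. They model mask
structure only, not DWI/ADC intensities.

``corrupt`` turns a ground-truth phantom into an imperfect "segmenter"
output by applying, in a fixed order: per-lesion drops, boundary
erosion/dilation, false-positive blob insertion, and independent voxel
flips. The fixed stage order keeps composed effects reproducible and
attributable. ``make_challenge_fixture`` composes generators, corruption,
the metric suite and the long-form metric table into a full synthetic
challenge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from strokekit.instances import DEFAULT_CONNECTIVITY, InstanceLabeling, label_components
from strokekit.phenotype import TERRITORY_TIEBREAK_ORDER, TerritoryAtlas
from strokekit.seg_metrics import evaluate_case
from strokekit.volumes_io import GridGeometry, LesionMask

__all__ = [
    "PhantomSpec",
    "CorruptionSpec",
    "make_phantom",
    "corrupt",
    "make_toy_atlas",
    "make_challenge_fixture",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic multi-lesion phantom.

    Lesion volumes are log-normal with median ``volume_median_ml`` and
    log-sd ``volume_log_sd`` (defaults 4 ml / 1.2, chosen to populate all
    three clinical size bins: <5, 5-20, >=20 ml). ``lesion_count`` is fixed
    when ``poisson_mean`` is None, else Poisson (at least 1). Placement
    keeps lesions separated by ``min_separation_vox`` background voxels, so
    the realized component count equals the requested count.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    lesion_count: int = 1
    poisson_mean: float | None = None
    volume_median_ml: float = 4.0
    volume_log_sd: float = 1.2
    min_separation_vox: int = 2
    confine_to_label: int | None = None
    seed: int = 0

    def geometry(self) -> GridGeometry:
        return GridGeometry(shape=self.shape, spacing=self.spacing)


@dataclass(frozen=True)
class CorruptionSpec:
    """Parameters of a simulated imperfect segmenter.

    Stages apply in this order: per-lesion drop with probability
    ``drop_probability``; boundary morphology (``morph_radius_vox`` voxels,
    positive = dilation, negative = erosion); insertion of
    Poisson(``fp_rate``) false-positive blobs with log-normal volumes;
    independent voxel flips with probability ``flip_probability``.
    """

    drop_probability: float = 0.0
    morph_radius_vox: int = 0
    fp_rate: float = 0.0
    fp_volume_median_ml: float = 0.5
    fp_volume_log_sd: float = 0.5
    flip_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drop_probability", "flip_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")


def _ellipsoid_offsets(n_voxels: int, axis_ratios: np.ndarray) -> np.ndarray:
    """Integer voxel offsets of a centered ellipsoid with ~n_voxels voxels."""
    # solve for base radius r so that (4/3)π r³ ∏ratios ≈ n_voxels
    r = (3.0 * n_voxels / (4.0 * np.pi * np.prod(axis_ratios))) ** (1.0 / 3.0)
    radii = np.maximum(r * axis_ratios, 0.5)
    ri = np.ceil(radii).astype(int)
    grids = np.mgrid[-ri[0]:ri[0] + 1, -ri[1]:ri[1] + 1, -ri[2]:ri[2] + 1]
    inside = (grids[0] / radii[0]) ** 2 + (grids[1] / radii[1]) ** 2 + (grids[2] / radii[2]) ** 2 <= 1.0
    return np.argwhere(inside) - ri


def make_phantom(spec: PhantomSpec, atlas: TerritoryAtlas | None = None,
                 max_retries: int = 200) -> tuple[LesionMask, InstanceLabeling]:
    """Generate a multi-lesion phantom mask plus its instance labeling.

    Lesions are rasterized as ellipsoids with random axis ratios in
    [0.6, 1.4]. Raises ``RuntimeError`` when a lesion cannot be placed
    within ``max_retries`` attempts (infeasible spec).
    """
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry()
    vox_ml = geom.voxel_volume_ml

    if spec.poisson_mean is not None:
        k = max(1, int(rng.poisson(spec.poisson_mean)))
    else:
        k = spec.lesion_count

    volume = np.zeros(geom.shape, dtype=np.uint8)
    # forbidden = dilation of existing lesions by the separation margin
    forbidden = np.zeros(geom.shape, dtype=bool)
    sep_structure = ndimage.generate_binary_structure(3, 3)

    if atlas is not None and spec.confine_to_label is not None:
        allowed_region = atlas.labels == spec.confine_to_label
    else:
        allowed_region = np.ones(geom.shape, dtype=bool)

    # cap volume draws at the largest ellipsoid that can fit the grid with
    # margin, so the heavy log-normal tail cannot make placement infeasible
    r_fit = (min(geom.shape) / 2.0 - spec.min_separation_vox - 1) / 1.4
    cap_vox = max(1, int(0.9 * (4.0 / 3.0) * np.pi * r_fit**3))

    # draw all volumes first and place largest-first: big lesions are the
    # hardest to fit, so packing them before the forbidden zone grows keeps
    # feasible specs feasible
    targets_ml = rng.lognormal(mean=np.log(spec.volume_median_ml),
                               sigma=spec.volume_log_sd, size=k)
    for target_ml in np.sort(targets_ml)[::-1]:
        n_vox = min(cap_vox, max(1, int(round(target_ml / vox_ml))))
        ratios = rng.uniform(0.6, 1.4, size=3)

        # when a lesion cannot be placed, halve it and try again: stochastic
        # volume draws should not make a reasonable spec fail, and the
        # realized per-lesion volumes are whatever the labeling reports
        placed = False
        while n_vox >= 1 and not placed:
            offsets = _ellipsoid_offsets(n_vox, ratios)
            lo = -offsets.min(axis=0)
            hi = np.array(geom.shape) - offsets.max(axis=0)
            if (lo >= hi).any():
                n_vox //= 2
                continue
            for _ in range(max_retries):
                center = rng.integers(lo, hi)
                coords = offsets + center
                ix = tuple(coords.T)
                if not allowed_region[ix].all():
                    continue
                if forbidden[ix].any():
                    continue
                volume[ix] = 1
                blob = np.zeros(geom.shape, dtype=bool)
                blob[ix] = True
                forbidden |= ndimage.binary_dilation(
                    blob, structure=sep_structure, iterations=max(1, spec.min_separation_vox))
                placed = True
                break
            else:
                n_vox //= 2
        if not placed:
            raise RuntimeError(
                f"could not place a lesion after {max_retries} retries per size, "
                "down to a single voxel; spec is infeasible for this grid")

    mask = LesionMask(geometry=geom, voxels=volume)
    return mask, label_components(mask, DEFAULT_CONNECTIVITY)


def corrupt(mask: LesionMask, spec: CorruptionSpec) -> LesionMask:
    """Simulate an imperfect segmenter's output for a ground-truth mask."""
    rng = np.random.default_rng(spec.seed)
    geom = mask.geometry
    out = mask.voxels.astype(bool)

    # 1. per-lesion drops
    if spec.drop_probability > 0:
        labeling = label_components(mask, DEFAULT_CONNECTIVITY)
        for inst in labeling.per_instance["instance_id"]:
            if rng.random() < spec.drop_probability:
                out[labeling.labels == inst] = False

    # 2. boundary morphology
    if spec.morph_radius_vox > 0:
        out = ndimage.binary_dilation(out, iterations=spec.morph_radius_vox)
    elif spec.morph_radius_vox < 0:
        out = ndimage.binary_erosion(out, iterations=-spec.morph_radius_vox)

    # 3. false-positive blob insertion
    n_fp = rng.poisson(spec.fp_rate)
    vox_ml = geom.voxel_volume_ml
    for _ in range(n_fp):
        target_ml = rng.lognormal(np.log(spec.fp_volume_median_ml), spec.fp_volume_log_sd)
        n_vox = max(1, int(round(target_ml / vox_ml)))
        offsets = _ellipsoid_offsets(n_vox, rng.uniform(0.6, 1.4, size=3))
        lo = -offsets.min(axis=0)
        hi = np.array(geom.shape) - offsets.max(axis=0)
        if (lo >= hi).any():
            continue  # blob larger than the grid; skip
        center = rng.integers(lo, hi)
        out[tuple((offsets + center).T)] = True

    # 4. independent voxel flips
    if spec.flip_probability > 0:
        flips = rng.random(geom.shape) < spec.flip_probability
        out = out ^ flips

    return LesionMask(geometry=geom, voxels=out.astype(np.uint8))


def make_toy_atlas(
    geometry: GridGeometry,
    layout: str = "axis_slabs",
    territory_names: Sequence[str] = TERRITORY_TIEBREAK_ORDER,
) -> TerritoryAtlas:
    """Partition the grid into contiguous labeled territories.

    ``axis_slabs`` slices the first axis into equal slabs, one per
    territory; ``nested_boxes`` assigns concentric rectangular shells.
    Every voxel gets a nonzero label, so out-of-atlas lesion load is always
    zero on these toys. This synthetic atlas stands in for an anatomical
    vascular-territory annotation (e.g. an annotated MNI template); it
    keeps the argmax-assignment logic testable, nothing more.
    """
    n = len(territory_names)
    if n < 2:
        raise ValueError("need at least 2 territories")
    if n > int(np.prod(geometry.shape)):
        raise ValueError("more territories than voxels")
    labels = np.zeros(geometry.shape, dtype=np.int32)

    if layout == "axis_slabs":
        edges = np.linspace(0, geometry.shape[0], n + 1).round().astype(int)
        for i in range(n):
            labels[edges[i]:edges[i + 1], :, :] = i + 1
    elif layout == "nested_boxes":
        center = (np.array(geometry.shape) - 1) / 2.0
        coords = np.indices(geometry.shape)
        # Chebyshev distance from center, normalized to [0, 1]
        cheb = np.max(np.abs(coords - center.reshape(3, 1, 1, 1)) /
                      np.maximum(center.reshape(3, 1, 1, 1), 1e-9), axis=0)
        shells = np.minimum((cheb * n).astype(int), n - 1)
        labels = (shells + 1).astype(np.int32)
    else:
        raise ValueError(f"unknown layout {layout!r}")

    names = {i + 1: name for i, name in enumerate(territory_names)}
    return TerritoryAtlas(geometry=geometry, labels=labels, names=names)


def make_challenge_fixture(
    n_cases: int,
    n_teams: int,
    quality_profiles: Mapping[str, CorruptionSpec] | None = None,
    seed: int = 0,
    phantom_spec: PhantomSpec | None = None,
    connectivity: int = DEFAULT_CONNECTIVITY,
):
    """Generate a full synthetic challenge: GT masks, team predictions, metrics.

    Each case is a fresh phantom; each team's prediction corrupts it with a
    team-specific :class:`CorruptionSpec` (default: teams of graded noise
    levels). Returns ``(gt_masks, team_masks, metric_frame)`` where
    ``metric_frame`` is the long-form (team, case_id, metric, value)
    DataFrame ready for :class:`strokekit.challenge_rank.MetricTable`.
    """
    if n_teams < 2:
        raise ValueError("need at least 2 teams")
    base = phantom_spec or PhantomSpec(poisson_mean=3.0)

    if quality_profiles is None:
        quality_profiles = {
            f"team_{i}": CorruptionSpec(drop_probability=0.05 * i,
                                        flip_probability=0.002 * i,
                                        fp_rate=0.5 * i)
            for i in range(n_teams)
        }
    if len(quality_profiles) != n_teams:
        raise ValueError("quality_profiles must have one entry per team")

    master = np.random.default_rng(seed)
    gt_masks: dict[str, LesionMask] = {}
    team_masks: dict[str, dict[str, LesionMask]] = {t: {} for t in quality_profiles}
    rows = []
    for i in range(n_cases):
        case_id = f"case_{i:03d}"
        gt, _ = make_phantom(replace(base, seed=int(master.integers(2**31))))
        gt_masks[case_id] = gt
        for team, prof in quality_profiles.items():
            pred = corrupt(gt, replace(prof, seed=int(master.integers(2**31))))
            team_masks[team][case_id] = pred
            cm = evaluate_case(pred, gt, connectivity)
            for metric, value in (("dsc", cm.dsc), ("lesion_f1", cm.lesion_f1),
                                  ("avd_ml", cm.avd_ml), ("ald", cm.ald)):
                rows.append({"team": team, "case_id": case_id,
                             "metric": metric, "value": float(value)})

    return gt_masks, team_masks, pd.DataFrame(rows)
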