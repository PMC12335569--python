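"""Domain types for binary lesion masks and NIfTI reading/writing.

A :class:`LesionMask` couples a 3D ``{0,1}`` voxel array with its
:class:`GridGeometry` (shape, mm spacing, orientation). Geometry is the
source of truth for every volume quantity downstream: a voxel's volume in
ml is ``prod(spacing)/1000``, which feeds the absolute-volume-difference
metric and the 5/20 ml size-bin thresholds.

Masks are evaluated in the grid they arrive in; prediction/ground-truth
pairs must share shape, and spacing mismatch beyond ``SPACING_ATOL_MM``
is an error rather than a silent resample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import nibabel as nib
import numpy as np

__all__ = [
    "GridGeometry",
    "LesionMask",
    "read_mask",
    "write_mask",
    "binarize",
    "mask_volume_ml",
    "check_compatible",
]

#: Maximum per-axis spacing disagreement (mm) tolerated between paired masks.
SPACING_ATOL_MM = 1e-3

#: Default binarization threshold for probability-map inputs.
DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class GridGeometry:
    """Voxel grid geometry: shape, per-axis spacing in mm, orientation tag.

    ``orientation_tag`` is an opaque value (here: the 4x4 affine as a tuple)
    carried through I/O round-trips so written files keep their pose. Two
    geometries with different tags but equal shape/spacing are still
    *compatible* for metric computation.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    orientation_tag: Any = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError(f"geometry must be 3D, got shape {self.shape}")
        if any(int(s) < 1 for s in self.shape):
            raise ValueError(f"all shape entries must be >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals (mm), got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        # 1 ml = 1 cm^3 = 1000 mm^3
        return self.voxel_volume_mm3 / 1000.0

    def affine(self) -> np.ndarray:
        """4x4 affine for writing: the stored one, or diag(spacing) if none."""
        if self.orientation_tag is not None:
            return np.asarray(self.orientation_tag, dtype=float).reshape(4, 4)
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.spacing
        return aff


@dataclass(frozen=True)
class LesionMask:
    """A 3D binary lesion mask on a voxel grid."""

    geometry: GridGeometry
    voxels: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.shape != self.geometry.shape:
            raise ValueError(
                f"voxel array shape {vox.shape} != geometry shape {self.geometry.shape}"
            )
        if not np.isin(vox, (0, 1)).all():
            raise ValueError("mask voxels must contain only 0 or 1")
        object.__setattr__(self, "voxels", np.ascontiguousarray(vox, dtype=np.uint8))

    @property
    def foreground_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def total_volume_ml(self) -> float:
        return self.foreground_voxels * self.geometry.voxel_volume_ml


def binarize(volume: np.ndarray, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Threshold a real-valued volume to {0,1}: output is 1 where value >= threshold.

    Idempotent on already-binary data at the default threshold.
    Raises ``ValueError`` on non-finite input.
    """
    vol = np.asarray(volume)
    if not np.isfinite(vol).all():
        raise ValueError("volume contains non-finite values (NaN/Inf); cannot binarize")
    return (vol >= threshold).astype(np.uint8)


def mask_volume_ml(mask: LesionMask) -> float:
    """Total lesion volume in ml: foreground voxel count x voxel volume."""
    return mask.total_volume_ml


def read_mask(path: str | os.PathLike, threshold: float = DEFAULT_THRESHOLD) -> LesionMask:
    """Read a NIfTI volume as a binary lesion mask.

    Spacing is taken as the per-axis Euclidean norms of the affine's first
    three columns, which is robust to rotation-only affines. Values are
    binarized with :func:`binarize`.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape} from {path}")
    affine = np.asarray(img.affine, dtype=float)
    spacing = tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))
    geom = GridGeometry(shape=data.shape, spacing=spacing, orientation_tag=tuple(map(tuple, affine)))
    return LesionMask(geometry=geom, voxels=binarize(data.astype(float), threshold))


def write_mask(mask: LesionMask, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI, preserving the affine/spacing."""
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.geometry.affine())
    img.header.set_zooms(mask.geometry.spacing)
    nib.save(img, str(path))


def check_compatible(a: LesionMask, b: LesionMask) -> None:
    """Validate that two masks live on comparable grids.

    Shapes must match exactly; spacings must agree to within
    ``SPACING_ATOL_MM`` per axis. Resampling is deliberately out of scope.
    """
    if a.geometry.shape != b.geometry.shape:
        raise ValueError(
            f"mask shape mismatch: {a.geometry.shape} vs {b.geometry.shape}"
        )
    sa, sb = np.asarray(a.geometry.spacing), np.asarray(b.geometry.spacing)
    if np.abs(sa - sb).max() > SPACING_ATOL_MM:
        raise ValueError(
            f"mask spacing mismatch beyond {SPACING_ATOL_MM} mm: {a.geometry.spacing} vs {b.geometry.spacing}"
        )
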