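from __future__ import annotations

import numpy as np
import pytest

from strokekit.volumes_io import GridGeometry, LesionMask


def mask_from(arr: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LesionMask:
    arr = np.asarray(arr)
    geom = GridGeometry(shape=arr.shape, spacing=spacing)
    return LesionMask(geometry=geom, voxels=(arr > 0).astype(np.uint8))


def cube_mask(shape, corners_and_sizes, spacing=(1.0, 1.0, 1.0)) -> LesionMask:
    """Mask with axis-aligned cubes: [(corner_xyz, size), ...]."""
    vol = np.zeros(shape, dtype=np.uint8)
    for (x, y, z), s in corners_and_sizes:
        vol[x:x + s, y:y + s, z:z + s] = 1
    return mask_from(vol, spacing)


def random_mask(rng: np.random.Generator, shape=(20, 20, 20), density=0.2,
                spacing=(1.0, 1.0, 1.0)) -> LesionMask:
    return mask_from(rng.random(shape) < density, spacing)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20220905)
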