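"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid scipy.ndimage and the package's own labeling: the
flood fill is a plain BFS over explicit neighbor offsets, and the
lesion-matching oracle builds the full instance-overlap matrix by voxel
enumeration.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(voxels: np.ndarray, connectivity: int) -> list[frozenset[int]]:
    """Partition foreground voxels into connected components by BFS.

    Returns a list of components, each a frozenset of flat (C-order) voxel
    indices; order of the list is arbitrary.
    """
    shape = voxels.shape
    offs = neighbor_offsets(connectivity)
    fg = {tuple(c) for c in np.argwhere(voxels)}
    seen: set[tuple[int, int, int]] = set()
    components = []
    for start in sorted(fg):
        if start in seen:
            continue
        comp = []
        queue = deque([start])
        seen.add(start)
        while queue:
            x, y, z = queue.popleft()
            comp.append(np.ravel_multi_index((x, y, z), shape))
            for dx, dy, dz in offs:
                nb = (x + dx, y + dy, z + dz)
                if nb in fg and nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        components.append(frozenset(int(i) for i in comp))
    return components


def partition_of_labeling(labels: np.ndarray) -> set[frozenset[int]]:
    """Canonical partition (set of flat-index frozensets) of a label volume."""
    out = set()
    for lab in np.unique(labels):
        if lab == 0:
            continue
        out.add(frozenset(int(i) for i in np.flatnonzero(labels == lab)))
    return out


def f1_by_overlap_matrix(pred_components: list[frozenset[int]],
                         gt_components: list[frozenset[int]]) -> tuple[float, int, int, int]:
    """Lesion detection F1 from the exhaustive pairwise overlap matrix."""
    overlap = np.zeros((len(gt_components), len(pred_components)), dtype=int)
    for i, g in enumerate(gt_components):
        for j, p in enumerate(pred_components):
            overlap[i, j] = len(g & p)
    tp = int((overlap.sum(axis=1) > 0).sum()) if overlap.size else 0
    fn = len(gt_components) - tp
    fp = int((overlap.sum(axis=0) == 0).sum()) if overlap.size else len(pred_components)
    if tp + fp + fn == 0:
        return 1.0, 0, 0, 0
    return 2.0 * tp / (2.0 * tp + fp + fn), tp, fp, fn
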