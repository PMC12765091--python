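"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the implementation's code paths:
surfaces are found by explicit neighbour checks, distances by full O(n²)
pairwise enumeration, and DSC by direct voxel counting on the arrays.
"""

import numpy as np
import pytest

from oar_sentinel.core import StructureMask, VolumeGrid


@pytest.fixture
def unit_grid():
    """8³ lattice at 1 mm isotropic spacing."""
    return VolumeGrid(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0))


def mask_from_indices(grid, indices, organ_id="organ"):
    occ = np.zeros(grid.shape, dtype=bool)
    for idx in indices:
        occ[tuple(idx)] = True
    return StructureMask(organ_id, grid, occ)


def random_mask(rng, grid, max_voxels=1000, organ_id="organ"):
    """Random blobby mask with at most ``max_voxels`` occupied voxels."""
    occ = np.zeros(grid.shape, dtype=bool)
    n_seeds = rng.integers(1, 4)
    for _ in range(n_seeds):
        c = rng.integers(0, grid.shape, size=3)
        r = rng.integers(1, 4)
        sl = tuple(
            slice(max(0, c[k] - r), min(grid.shape[k], c[k] + r + 1)) for k in range(3)
        )
        occ[sl] = rng.random(occ[sl].shape) > 0.3
    if occ.sum() > max_voxels:
        keep = np.argwhere(occ)[:max_voxels]
        occ = np.zeros(grid.shape, dtype=bool)
        occ[tuple(keep.T)] = True
    if not occ.any():
        occ[tuple(rng.integers(0, grid.shape, size=3))] = True
    return StructureMask(organ_id, grid, occ)


# --- oracles ---------------------------------------------------------------


def dsc_oracle(a_occ, b_occ):
    """Dice by direct voxel counting."""
    inter = 0
    na = nb = 0
    flat_a = a_occ.ravel()
    flat_b = b_occ.ravel()
    for va, vb in zip(flat_a, flat_b):
        na += bool(va)
        nb += bool(vb)
        inter += bool(va) and bool(vb)
    if na + nb == 0:
        return None
    return 2.0 * inter / (na + nb)


def surface_points_oracle(mask):
    """Surface voxel centres by explicit 6-neighbour checks."""
    occ = mask.occupancy
    pts = []
    for idx in np.argwhere(occ):
        i, j, k = idx
        exposed = False
        for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            ni, nj, nk = i + d[0], j + d[1], k + d[2]
            if not (0 <= ni < occ.shape[0] and 0 <= nj < occ.shape[1] and 0 <= nk < occ.shape[2]):
                exposed = True
                break
            if not occ[ni, nj, nk]:
                exposed = True
                break
        if exposed:
            pts.append(
                [mask.grid.origin[a] + idx[a] * mask.grid.spacing[a] for a in range(3)]
            )
    return np.asarray(pts, dtype=float)


def hdd95_oracle(a, b, percentile=95.0):
    """Pooled symmetric 95th-percentile surface distance, all pairs O(n²)."""
    pa = surface_points_oracle(a)
    pb = surface_points_oracle(b)
    diff = pa[:, None, :] - pb[None, :, :]
    dmat = np.sqrt((diff**2).sum(axis=2))
    pooled = np.concatenate([dmat.min(axis=1), dmat.min(axis=0)])
    return float(np.percentile(pooled, percentile))
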