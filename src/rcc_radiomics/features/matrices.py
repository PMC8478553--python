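"""Builders for the five 3D texture matrices.

All builders operate on a gray-level image (integer levels 1..Ng inside
the mask, 0 outside).  GLCM and GLRLM are directional and use the 13
unique 3D direction pairs at distance 1; GLSZM zones, GLDM dependences
and NGTDM neighborhoods use full 26-connectivity.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def unique_directions_3d() -> list[tuple[int, int, int]]:
    """The 13 unique distance-1 direction pairs in 3D.

    Of the 26 neighbor offsets, one of each +/- pair is kept (the one
    whose first nonzero component is positive).
    """
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                off = (dz, dy, dx)
                if off == (0, 0, 0):
                    continue
                first = next(o for o in off if o != 0)
                if first > 0:
                    dirs.append(off)
    assert len(dirs) == 13
    return dirs


def all_neighbor_offsets_3d() -> list[tuple[int, int, int]]:
    """All 26 neighbor offsets."""
    dirs = unique_directions_3d()
    return dirs + [(-a, -b, -c) for (a, b, c) in dirs]


def _shifted_views(arr: np.ndarray, off):
    """Views (a, b) such that a[i] and b[i] sit ``off`` apart in ``arr``."""
    s1, s2 = [], []
    for n, o in zip(arr.shape, off):
        s1.append(slice(max(0, -o), n - max(0, o)))
        s2.append(slice(max(0, o), n - max(0, -o)))
    return arr[tuple(s1)], arr[tuple(s2)]


def glcm_matrices(levels: np.ndarray, ng: int) -> np.ndarray:
    """Symmetric co-occurrence count matrices, shape (13, ng, ng).

    A pair is counted when both voxels are inside the mask (level > 0);
    symmetric accumulation counts each unordered pair in both orders.
    """
    out = np.zeros((13, ng, ng), dtype=np.int64)
    for d, off in enumerate(unique_directions_3d()):
        a, b = _shifted_views(levels, off)
        valid = (a > 0) & (b > 0)
        ai, bi = a[valid] - 1, b[valid] - 1
        np.add.at(out[d], (ai, bi), 1)
        np.add.at(out[d], (bi, ai), 1)
    return out


def glrlm_matrices(levels: np.ndarray, ng: int) -> list[np.ndarray]:
    """Run-length count matrices, one (ng, max_run) array per direction.

    A run is a maximal set of collinear, consecutive voxels sharing one
    gray level; out-of-mask voxels (level 0) break runs.
    """
    shape = levels.shape
    flat = levels.ravel()
    coords = np.indices(shape).reshape(3, -1)
    big = 3 * max(shape)
    result = []
    for off in unique_directions_3d():
        off_a = np.array(off).reshape(3, 1)
        axis = next(i for i, o in enumerate(off) if o != 0)  # off[axis] == +1
        t = coords[axis]
        start = coords - t * off_a  # line identifier (may be negative)
        key = ((start[0] + big) * (4 * big) + (start[1] + big)) * (4 * big) + (
            start[2] + big
        )
        order = np.lexsort((t, key))
        lv = flat[order]
        ky = key[order]
        # run boundaries: new line or new gray level
        brk = np.empty(lv.size, dtype=bool)
        brk[0] = True
        brk[1:] = (ky[1:] != ky[:-1]) | (lv[1:] != lv[:-1])
        starts = np.flatnonzero(brk)
        lengths = np.diff(np.append(starts, lv.size))
        run_levels = lv[starts]
        keep = run_levels > 0
        run_levels, lengths = run_levels[keep], lengths[keep]
        max_len = int(lengths.max()) if lengths.size else 1
        mat = np.zeros((ng, max_len), dtype=np.int64)
        np.add.at(mat, (run_levels - 1, lengths - 1), 1)
        result.append(mat)
    return result


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone count matrix, shape (ng, max_zone_size).

    A zone is a 26-connected component of voxels sharing one gray level.
    """
    structure = np.ones((3, 3, 3), dtype=int)
    zone_sizes: list[tuple[int, int]] = []  # (level, size)
    for lev in range(1, ng + 1):
        lab, nlab = ndimage.label(levels == lev, structure=structure)
        if nlab:
            sizes = np.bincount(lab.ravel())[1:]
            zone_sizes.extend((lev, int(s)) for s in sizes)
    max_size = max(s for _, s in zone_sizes)
    mat = np.zeros((ng, max_size), dtype=np.int64)
    for lev, s in zone_sizes:
        mat[lev - 1, s - 1] += 1
    return mat


def gldm_matrix(levels: np.ndarray, ng: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix, shape (ng, 27).

    Column ``d`` counts voxels of each gray level having exactly ``d``
    of their 26 neighbors inside the mask with ``|level diff| <= alpha``.
    Feature formulas use dependence size ``d + 1`` (center included) so
    isolated voxels contribute at size 1 rather than dividing by zero.
    """
    mask = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in all_neighbor_offsets_3d():
        a, b = _shifted_views(levels, off)
        ma, mb = _shifted_views(mask, off)
        contrib = np.zeros_like(a)
        contrib[ma & mb & (np.abs(a - b) <= alpha)] = 1
        s1 = tuple(
            slice(max(0, -o), n - max(0, o)) for n, o in zip(levels.shape, off)
        )
        dep[s1] += contrib
    mat = np.zeros((ng, 27), dtype=np.int64)
    np.add.at(mat, (levels[mask] - 1, dep[mask]), 1)
    return mat


def ngtdm_table(levels: np.ndarray, ng: int):
    """NGTDM per-level sums.

    Returns ``(s, n)`` where ``s[i]`` is the summed absolute difference
    between level ``i+1`` voxels and the mean level of their in-mask
    26-neighborhood, and ``n[i]`` is the voxel count at that level.
    Voxels without any in-mask neighbor contribute 0 to ``s``.
    """
    mask = levels > 0
    nsum = np.zeros(levels.shape, dtype=np.float64)
    ncnt = np.zeros(levels.shape, dtype=np.int64)
    for off in all_neighbor_offsets_3d():
        a, b = _shifted_views(levels, off)
        mb = _shifted_views(mask, off)[1]
        s1 = tuple(
            slice(max(0, -o), n - max(0, o)) for n, o in zip(levels.shape, off)
        )
        nsum[s1] += np.where(mb, b, 0)
        ncnt[s1] += mb
    s = np.zeros(ng, dtype=np.float64)
    n = np.zeros(ng, dtype=np.int64)
    has_nb = mask & (ncnt > 0)
    diffs = np.abs(levels[has_nb] - nsum[has_nb] / ncnt[has_nb])
    np.add.at(s, levels[has_nb] - 1, diffs)
    np.add.at(n, levels[mask] - 1, 1)
    return s, n
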