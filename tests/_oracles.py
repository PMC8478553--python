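"""Brute-force oracles for feature extraction, written as plain loops.

These deliberately avoid the vectorized code paths of the package: every
matrix is built by exhaustive enumeration (voxel pairs, run walks, BFS
zones, neighbor loops) and every feature by direct transcription of its
defining formula.  They are only practical on tiny volumes (<= 5^3).
"""

from __future__ import annotations

import math

import numpy as np

DIRS_13 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
    and next(o for o in (dz, dy, dx) if o != 0) > 0
]
DIRS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def _inside(shape, z, y, x):
    return 0 <= z < shape[0] and 0 <= y < shape[1] and 0 <= x < shape[2]


# ---------------------------------------------------------------------- GLCM


def glcm_matrix_oracle(levels, ng, direction):
    """Symmetric co-occurrence counts by looping over all voxel pairs."""
    shape = levels.shape
    P = np.zeros((ng, ng))
    dz, dy, dx = direction
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                a = levels[z, y, x]
                if a == 0 or not _inside(shape, z + dz, y + dy, x + dx):
                    continue
                b = levels[z + dz, y + dy, x + dx]
                if b == 0:
                    continue
                P[a - 1, b - 1] += 1
                P[b - 1, a - 1] += 1
    return P


def glcm_features_oracle(levels, ng):
    per_dir = []
    for d in DIRS_13:
        P = glcm_matrix_oracle(levels, ng, d)
        if P.sum() == 0:
            continue
        P = P / P.sum()
        per_dir.append(_glcm_feats_naive(P))
    keys = per_dir[0].keys()
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in keys}


def _glcm_feats_naive(P):
    ng = P.shape[0]
    g = range(ng)
    px = [sum(P[i][j] for j in g) for i in g]
    mu = sum((i + 1) * px[i] for i in g)
    var = sum(((i + 1) - mu) ** 2 * px[i] for i in g)
    sigma = math.sqrt(var)

    pdiff = [0.0] * ng
    psum = [0.0] * (2 * ng + 1)
    for i in g:
        for j in g:
            pdiff[abs(i - j)] += P[i][j]
            psum[i + j + 2] += P[i][j]
    da = sum(k * pdiff[k] for k in range(ng))

    def h(vals):
        return -sum(v * math.log2(v) for v in vals if v > 0)

    hx = h(px)
    hxy = h([P[i][j] for i in g for j in g])
    hxy1 = -sum(
        P[i][j] * math.log2(px[i] * px[j])
        for i in g
        for j in g
        if P[i][j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = h([px[i] * px[j] for i in g for j in g])

    present = [i for i in g if px[i] > 0]
    if len(present) > 1:
        Q = np.zeros((len(present), len(present)))
        for a, i in enumerate(present):
            for b, j in enumerate(present):
                Q[a, b] = sum(
                    P[i][k] * P[j][k] / (px[i] * px[k]) for k in present
                )
        eig = sorted(np.linalg.eigvals(Q).real, reverse=True)
        mcc = math.sqrt(max(eig[1], 0.0))
    else:
        mcc = 1.0

    corr = (
        (sum((i + 1) * (j + 1) * P[i][j] for i in g for j in g) - mu * mu)
        / (sigma * sigma)
        if var > 0
        else 1.0
    )

    return {
        "glcm_autocorrelation": sum((i + 1) * (j + 1) * P[i][j] for i in g for j in g),
        "glcm_joint_average": mu,
        "glcm_cluster_prominence": sum(
            ((i + 1) + (j + 1) - 2 * mu) ** 4 * P[i][j] for i in g for j in g
        ),
        "glcm_cluster_shade": sum(
            ((i + 1) + (j + 1) - 2 * mu) ** 3 * P[i][j] for i in g for j in g
        ),
        "glcm_cluster_tendency": sum(
            ((i + 1) + (j + 1) - 2 * mu) ** 2 * P[i][j] for i in g for j in g
        ),
        "glcm_contrast": sum((i - j) ** 2 * P[i][j] for i in g for j in g),
        "glcm_correlation": corr,
        "glcm_difference_average": da,
        "glcm_difference_entropy": h(pdiff),
        "glcm_difference_variance": sum(
            (k - da) ** 2 * pdiff[k] for k in range(ng)
        ),
        "glcm_joint_energy": sum(P[i][j] ** 2 for i in g for j in g),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
        "glcm_imc2": math.sqrt(1 - math.exp(-2 * max(hxy2 - hxy, 0.0))),
        "glcm_idm": sum(P[i][j] / (1 + (i - j) ** 2) for i in g for j in g),
        "glcm_idmn": sum(
            P[i][j] / (1 + ((i - j) / ng) ** 2) for i in g for j in g
        ),
        "glcm_id": sum(P[i][j] / (1 + abs(i - j)) for i in g for j in g),
        "glcm_idn": sum(P[i][j] / (1 + abs(i - j) / ng) for i in g for j in g),
        "glcm_inverse_variance": sum(
            P[i][j] / (i - j) ** 2 for i in g for j in g if i != j
        ),
        "glcm_maximum_probability": max(P[i][j] for i in g for j in g),
        "glcm_sum_entropy": h(psum),
        "glcm_sum_squares": var,
        "glcm_mcc": mcc,
    }


# --------------------------------------------------------------------- GLRLM


def glrlm_matrix_oracle(levels, ng, direction):
    """Run-length counts by walking every maximal run once."""
    shape = levels.shape
    runs = {}
    dz, dy, dx = direction
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                lev = levels[z, y, x]
                if lev == 0:
                    continue
                pz, py, px_ = z - dz, y - dy, x - dx
                if _inside(shape, pz, py, px_) and levels[pz, py, px_] == lev:
                    continue  # not a run start
                length = 1
                nz, ny, nx = z + dz, y + dy, x + dx
                while _inside(shape, nz, ny, nx) and levels[nz, ny, nx] == lev:
                    length += 1
                    nz, ny, nx = nz + dz, ny + dy, nx + dx
                runs[(lev, length)] = runs.get((lev, length), 0) + 1
    max_len = max((l for (_, l) in runs), default=1)
    R = np.zeros((ng, max_len))
    for (lev, l), c in runs.items():
        R[lev - 1, l - 1] = c
    return R


def run_zone_features_oracle(mat, n_voxels, names):
    nr = mat.sum()
    ng, nl = mat.shape
    p = mat / nr
    mu_i = sum((i + 1) * p[i][j] for i in range(ng) for j in range(nl))
    mu_j = sum((j + 1) * p[i][j] for i in range(ng) for j in range(nl))
    vals = [
        sum(p[i][j] / (j + 1) ** 2 for i in range(ng) for j in range(nl)),
        sum(p[i][j] * (j + 1) ** 2 for i in range(ng) for j in range(nl)),
        sum(sum(mat[i]) ** 2 for i in range(ng)) / nr,
        sum(sum(p[i]) ** 2 for i in range(ng)),
        sum(sum(mat[:, j]) ** 2 for j in range(nl)) / nr,
        sum(sum(p[:, j]) ** 2 for j in range(nl)),
        nr / n_voxels,
        sum(p[i][j] * ((i + 1) - mu_i) ** 2 for i in range(ng) for j in range(nl)),
        sum(p[i][j] * ((j + 1) - mu_j) ** 2 for i in range(ng) for j in range(nl)),
        -sum(
            p[i][j] * math.log2(p[i][j])
            for i in range(ng)
            for j in range(nl)
            if p[i][j] > 0
        ),
        sum(p[i][j] / (i + 1) ** 2 for i in range(ng) for j in range(nl)),
        sum(p[i][j] * (i + 1) ** 2 for i in range(ng) for j in range(nl)),
        sum(
            p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ng)
            for j in range(nl)
        ),
        sum(
            p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ng)
            for j in range(nl)
        ),
        sum(
            p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ng)
            for j in range(nl)
        ),
        sum(
            p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ng)
            for j in range(nl)
        ),
    ]
    return dict(zip(names, vals))


def glrlm_features_oracle(levels, ng, n_voxels, names):
    per_dir = []
    for d in DIRS_13:
        R = glrlm_matrix_oracle(levels, ng, d)
        if R.sum() > 0:
            per_dir.append(run_zone_features_oracle(R, n_voxels, names))
    return {k: sum(f[k] for f in per_dir) / len(per_dir) for k in names}


# --------------------------------------------------------------------- GLSZM


def glszm_matrix_oracle(levels, ng):
    """Zone sizes by BFS flood fill with 26-connectivity."""
    shape = levels.shape
    seen = np.zeros(shape, dtype=bool)
    zones = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if levels[z, y, x] == 0 or seen[z, y, x]:
                    continue
                lev = levels[z, y, x]
                stack = [(z, y, x)]
                seen[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in DIRS_26:
                        nz, ny, nx = cz + dz, cy + dy, cx + dx
                        if (
                            _inside(shape, nz, ny, nx)
                            and not seen[nz, ny, nx]
                            and levels[nz, ny, nx] == lev
                        ):
                            seen[nz, ny, nx] = True
                            stack.append((nz, ny, nx))
                zones.append((lev, size))
    max_size = max(s for _, s in zones)
    Z = np.zeros((ng, max_size))
    for lev, s in zones:
        Z[lev - 1, s - 1] += 1
    return Z


# ---------------------------------------------------------------------- GLDM


def gldm_matrix_oracle(levels, ng, alpha=0):
    shape = levels.shape
    D = np.zeros((ng, 27))
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                lev = levels[z, y, x]
                if lev == 0:
                    continue
                dep = 0
                for dz, dy, dx in DIRS_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if (
                        _inside(shape, nz, ny, nx)
                        and levels[nz, ny, nx] != 0
                        and abs(int(levels[nz, ny, nx]) - int(lev)) <= alpha
                    ):
                        dep += 1
                D[lev - 1, dep] += 1
    return D


def gldm_features_oracle(levels, ng, names, alpha=0):
    D = gldm_matrix_oracle(levels, ng, alpha)
    nz = D.sum()
    p = D / nz
    ngl, nd = p.shape
    mu_i = sum((i + 1) * p[i][j] for i in range(ngl) for j in range(nd))
    mu_j = sum((j + 1) * p[i][j] for i in range(ngl) for j in range(nd))
    vals = [
        sum(p[i][j] / (j + 1) ** 2 for i in range(ngl) for j in range(nd)),
        sum(p[i][j] * (j + 1) ** 2 for i in range(ngl) for j in range(nd)),
        sum(sum(D[i]) ** 2 for i in range(ngl)) / nz,
        sum(sum(D[:, j]) ** 2 for j in range(nd)) / nz,
        sum(sum(p[:, j]) ** 2 for j in range(nd)),
        sum(p[i][j] * ((i + 1) - mu_i) ** 2 for i in range(ngl) for j in range(nd)),
        sum(p[i][j] * ((j + 1) - mu_j) ** 2 for i in range(ngl) for j in range(nd)),
        -sum(
            p[i][j] * math.log2(p[i][j])
            for i in range(ngl)
            for j in range(nd)
            if p[i][j] > 0
        ),
        sum(p[i][j] / (i + 1) ** 2 for i in range(ngl) for j in range(nd)),
        sum(p[i][j] * (i + 1) ** 2 for i in range(ngl) for j in range(nd)),
        sum(
            p[i][j] / ((i + 1) ** 2 * (j + 1) ** 2)
            for i in range(ngl)
            for j in range(nd)
        ),
        sum(
            p[i][j] * (i + 1) ** 2 / (j + 1) ** 2
            for i in range(ngl)
            for j in range(nd)
        ),
        sum(
            p[i][j] * (j + 1) ** 2 / (i + 1) ** 2
            for i in range(ngl)
            for j in range(nd)
        ),
        sum(
            p[i][j] * (i + 1) ** 2 * (j + 1) ** 2
            for i in range(ngl)
            for j in range(nd)
        ),
    ]
    return dict(zip(names, vals))


# --------------------------------------------------------------------- NGTDM


def ngtdm_features_oracle(levels, ng, names):
    shape = levels.shape
    s = [0.0] * ng
    n = [0] * ng
    nv = 0
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                lev = levels[z, y, x]
                if lev == 0:
                    continue
                nv += 1
                n[lev - 1] += 1
                nb = []
                for dz, dy, dx in DIRS_26:
                    nz, ny, nx = z + dz, y + dy, x + dx
                    if _inside(shape, nz, ny, nx) and levels[nz, ny, nx] != 0:
                        nb.append(levels[nz, ny, nx])
                if nb:
                    s[lev - 1] += abs(lev - sum(nb) / len(nb))
    p = [c / nv for c in n]
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    ps_sum = sum(p[i] * s[i] for i in range(ng))
    coarseness = min(1 / ps_sum, 1e6) if ps_sum > 0 else 1e6
    if ngp > 1:
        contrast = (
            sum(
                p[i] * p[j] * (i - j) ** 2 for i in present for j in present
            )
            / (ngp * (ngp - 1))
            * (sum(s) / nv)
        )
        denom = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present
        )
        busyness = ps_sum / denom if denom > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                for i in present
                for j in present
            )
            / nv
        )
        s_tot = sum(s)
        strength = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
            / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0
    vals = [coarseness, contrast, busyness, complexity, strength]
    return dict(zip(names, vals))


# --------------------------------------------------------------- first order


def first_order_oracle(values, levels_in_mask, ng, voxel_volume):
    """18 first-order statistics by direct formula evaluation."""
    v = sorted(float(x) for x in values)
    n = len(v)
    mean = sum(v) / n
    var = sum((x - mean) ** 2 for x in v) / n
    m3 = sum((x - mean) ** 3 for x in v) / n
    m4 = sum((x - mean) ** 4 for x in v) / n
    counts = [0] * ng
    for lev in levels_in_mask:
        counts[lev - 1] += 1
    probs = [c / n for c in counts]
    p10, p25, p75, p90 = (float(np.percentile(values, q)) for q in (10, 25, 75, 90))
    robust = [x for x in v if p10 <= x <= p90]
    rmean = sum(robust) / len(robust)
    return {
        "fo_mean": mean,
        "fo_median": float(np.median(values)),
        "fo_minimum": v[0],
        "fo_maximum": v[-1],
        "fo_range": v[-1] - v[0],
        "fo_variance": var,
        "fo_skewness": m3 / var**1.5 if var > 0 else 0.0,
        "fo_kurtosis": m4 / var**2 if var > 0 else 0.0,
        "fo_energy": sum(x**2 for x in v),
        "fo_total_energy": voxel_volume * sum(x**2 for x in v),
        "fo_entropy": -sum(p * math.log2(p) for p in probs if p > 0),
        "fo_uniformity": sum(p**2 for p in probs),
        "fo_mad": sum(abs(x - mean) for x in v) / n,
        "fo_robust_mad": sum(abs(x - rmean) for x in robust) / len(robust),
        "fo_rms": math.sqrt(sum(x**2 for x in v) / n),
        "fo_p10": p10,
        "fo_p90": p90,
        "fo_iqr": p75 - p25,
    }


# -------------------------------------------------------------------- shape


def shape_features_oracle(mask, spacing=(1.0, 1.0, 1.0)):
    """The 13 shape features recomputed with explicit loops from the same
    marching-cubes mesh definition (level 0.5 on the padded mask)."""
    from skimage.measure import marching_cubes

    padded = np.pad(np.asarray(mask) > 0.5, 1).astype(float)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
    verts = verts.astype(float)

    area = 0.0
    vol6 = 0.0
    for f in faces:
        a, b, c = verts[f[0]], verts[f[1]], verts[f[2]]
        cross = np.cross(b - a, c - a)
        area += 0.5 * math.sqrt(float(cross @ cross))
        vol6 += float(a @ np.cross(b, c))
    vol = abs(vol6) / 6.0

    def max_d(points):
        best = 0.0
        for i in range(len(points)):
            for j in range(i + 1, len(points)):
                d = math.dist(points[i], points[j])
                best = max(best, d)
        return best

    pts = [tuple(v) for v in verts]
    d3 = max_d(pts)
    d_slice = max_d([(v[1], v[2]) for v in verts])
    d_col = max_d([(v[0], v[2]) for v in verts])
    d_row = max_d([(v[0], v[1]) for v in verts])

    coords = [
        (z * spacing[0], y * spacing[1], x * spacing[2])
        for (z, y, x) in np.argwhere(np.asarray(mask) > 0.5)
    ]
    n = len(coords)
    if n > 1:
        means = [sum(c[k] for c in coords) / n for k in range(3)]
        cov = np.zeros((3, 3))
        for c in coords:
            d = np.array(c) - means
            cov += np.outer(d, d)
        cov /= n - 1
        eig = sorted(np.linalg.eigvalsh(cov))
        eig = [max(e, 0.0) for e in eig]
        least, minor, major = (4 * math.sqrt(e) for e in eig)
        elong = math.sqrt(eig[1] / eig[2]) if eig[2] > 0 else 1.0
        flat = math.sqrt(eig[0] / eig[2]) if eig[2] > 0 else 1.0
    else:
        least = minor = major = 0.0
        elong = flat = 1.0

    return {
        "shape_mesh_volume": vol,
        "shape_surface_area": area,
        "shape_surface_volume_ratio": area / vol if vol > 0 else 0.0,
        "shape_sphericity": math.pi ** (1 / 3) * (6 * vol) ** (2 / 3) / area,
        "shape_max_3d_diameter": d3,
        "shape_max_2d_diameter_slice": d_slice,
        "shape_max_2d_diameter_column": d_col,
        "shape_max_2d_diameter_row": d_row,
        "shape_major_axis_length": major,
        "shape_minor_axis_length": minor,
        "shape_least_axis_length": least,
        "shape_elongation": elong,
        "shape_flatness": flat,
    }
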