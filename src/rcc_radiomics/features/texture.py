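"""Texture features computed from the five matrix families.

Feature rosters: 23 GLCM, 16 GLRLM, 16 GLSZM, 14 GLDM, 5 NGTDM.
Directional families (GLCM, GLRLM) are computed per direction and
averaged over the 13 directions; directions that produce no pairs/runs
(possible for very thin masks) are excluded from the average.

Degenerate single-gray-level regions never yield NaN: entropies and
contrasts are 0, uniformity-like features 1, GLCM correlation and MCC 1.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI
from .matrices import (
    glcm_matrices,
    gldm_matrix,
    glrlm_matrices,
    glszm_matrix,
    ngtdm_table,
)

GLCM_NAMES = (
    "glcm_autocorrelation",
    "glcm_joint_average",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_cluster_tendency",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_average",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_joint_energy",
    "glcm_joint_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_idm",
    "glcm_idmn",
    "glcm_id",
    "glcm_idn",
    "glcm_inverse_variance",
    "glcm_maximum_probability",
    "glcm_sum_entropy",
    "glcm_sum_squares",
    "glcm_mcc",
)

GLRLM_NAMES = (
    "glrlm_sre",
    "glrlm_lre",
    "glrlm_gln",
    "glrlm_glnn",
    "glrlm_rln",
    "glrlm_rlnn",
    "glrlm_run_percentage",
    "glrlm_glv",
    "glrlm_rv",
    "glrlm_run_entropy",
    "glrlm_lglre",
    "glrlm_hglre",
    "glrlm_srlgle",
    "glrlm_srhgle",
    "glrlm_lrlgle",
    "glrlm_lrhgle",
)

GLSZM_NAMES = (
    "glszm_sae",
    "glszm_lae",
    "glszm_gln",
    "glszm_glnn",
    "glszm_szn",
    "glszm_sznn",
    "glszm_zone_percentage",
    "glszm_glv",
    "glszm_zv",
    "glszm_zone_entropy",
    "glszm_lglze",
    "glszm_hglze",
    "glszm_salgle",
    "glszm_sahgle",
    "glszm_lalgle",
    "glszm_lahgle",
)

GLDM_NAMES = (
    "gldm_sde",
    "gldm_lde",
    "gldm_gln",
    "gldm_dn",
    "gldm_dnn",
    "gldm_glv",
    "gldm_dv",
    "gldm_de",
    "gldm_lgle",
    "gldm_hgle",
    "gldm_sdlgle",
    "gldm_sdhgle",
    "gldm_ldlgle",
    "gldm_ldhgle",
)

NGTDM_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)

_COARSENESS_CAP = 1e6  # limit for a flat region where sum(p*s) -> 0


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_features_single(p: np.ndarray) -> dict[str, float]:
    """Features of one normalized symmetric GLCM ``p`` (ng x ng)."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # symmetric => px == py
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng)
    p_diff = np.array([p[np.abs(ii - jj) == k].sum() for k in k_diff])
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.array([p[(ii + jj) == k].sum() for k in k_sum])

    da = float((k_diff * p_diff).sum())
    hx = float(-_xlog2(px).sum())
    hxy = float(-_xlog2(p).sum())
    outer = px[:, None] * px[None, :]
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = float(-_xlog2(outer).sum())
    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(1 - np.exp(-2.0 * max(hxy2 - hxy, 0.0))))

    if sigma2 > 0:
        correlation = float(((ii * jj * p).sum() - mu * mu) / (sigma * sigma))
    else:
        correlation = 1.0

    # MCC: second-largest eigenvalue of Q over the present levels
    present = px > 0
    if present.sum() > 1:
        ps = p[np.ix_(present, present)]
        pxs = px[present]
        q = (ps / pxs[:, None]) @ (ps / pxs[None, :]).T
        eig = np.sort(np.linalg.eigvals(q).real)[::-1]
        mcc = float(np.sqrt(max(eig[1], 0.0)))
    else:
        mcc = 1.0

    off_diag = np.abs(ii - jj) > 0
    inv_var = float((p[off_diag] / (ii - jj)[off_diag] ** 2).sum())

    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_joint_average": mu,
        "glcm_cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "glcm_cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_correlation": correlation,
        "glcm_difference_average": da,
        "glcm_difference_entropy": float(-_xlog2(p_diff).sum()),
        "glcm_difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "glcm_joint_energy": float((p**2).sum()),
        "glcm_joint_entropy": hxy,
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_idm": float((p / (1 + (ii - jj) ** 2)).sum()),
        "glcm_idmn": float((p / (1 + ((ii - jj) / ng) ** 2)).sum()),
        "glcm_id": float((p / (1 + np.abs(ii - jj))).sum()),
        "glcm_idn": float((p / (1 + np.abs(ii - jj) / ng)).sum()),
        "glcm_inverse_variance": inv_var,
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_entropy": float(-_xlog2(p_sum).sum()),
        "glcm_sum_squares": sigma2,
        "glcm_mcc": mcc,
    }


def glcm_features(roi: DiscretizedROI) -> dict[str, float]:
    """23 GLCM features averaged over the 13 directions."""
    mats = glcm_matrices(roi.levels, roi.ng)
    per_dir = []
    for m in mats:
        tot = m.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_features_single(m / tot))
    if not per_dir:
        raise ValueError("no voxel pairs in any direction (mask too small)")
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


def _run_zone_features(mat: np.ndarray, n_voxels: int, prefix: str, names) -> dict[str, float]:
    """Shared GLRLM/GLSZM feature formulas over a (levels x sizes) matrix."""
    nr = mat.sum()
    p = mat / nr
    ng_dim, sz_dim = mat.shape
    iv = np.arange(1, ng_dim + 1, dtype=float)
    jv = np.arange(1, sz_dim + 1, dtype=float)
    ii, jj = np.meshgrid(iv, jv, indexing="ij")
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    mu_i = float((iv * row).sum())
    mu_j = float((jv * col).sum())
    vals = {
        "s_small": float((p / jj**2).sum()),
        "s_large": float((p * jj**2).sum()),
        "gln": float((mat.sum(axis=1) ** 2).sum() / nr),
        "glnn": float((row**2).sum()),
        "sn": float((mat.sum(axis=0) ** 2).sum() / nr),
        "snn": float((col**2).sum()),
        "pct": float(nr / n_voxels),
        "glv": float((p * (ii - mu_i) ** 2).sum()),
        "sv": float((p * (jj - mu_j) ** 2).sum()),
        "entropy": float(-_xlog2(p).sum()),
        "lgl": float((p / ii**2).sum()),
        "hgl": float((p * ii**2).sum()),
        "sl": float((p / (ii**2 * jj**2)).sum()),
        "sh": float((p * ii**2 / jj**2).sum()),
        "ll": float((p * jj**2 / ii**2).sum()),
        "lh": float((p * ii**2 * jj**2).sum()),
    }
    return dict(zip(names, vals.values()))


def glrlm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 GLRLM features averaged over the 13 directions."""
    mats = glrlm_matrices(roi.levels, roi.ng)
    per_dir = [
        _run_zone_features(m, roi.n_voxels, "glrlm", GLRLM_NAMES)
        for m in mats
        if m.sum() > 0
    ]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


def glszm_features(roi: DiscretizedROI) -> dict[str, float]:
    """16 GLSZM features (26-connected zones)."""
    mat = glszm_matrix(roi.levels, roi.ng)
    return _run_zone_features(mat, roi.n_voxels, "glszm", GLSZM_NAMES)


def gldm_features(roi: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """14 GLDM features (26-neighborhood, dependence tolerance ``alpha``)."""
    mat = gldm_matrix(roi.levels, roi.ng, alpha=alpha)
    nz = mat.sum()
    p = mat / nz
    iv = np.arange(1, roi.ng + 1, dtype=float)
    jv = np.arange(1, 28, dtype=float)  # dependence size = neighbors + center
    ii, jj = np.meshgrid(iv, jv, indexing="ij")
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    mu_i = float((iv * row).sum())
    mu_j = float((jv * col).sum())
    return {
        "gldm_sde": float((p / jj**2).sum()),
        "gldm_lde": float((p * jj**2).sum()),
        "gldm_gln": float((mat.sum(axis=1) ** 2).sum() / nz),
        "gldm_dn": float((mat.sum(axis=0) ** 2).sum() / nz),
        "gldm_dnn": float((col**2).sum()),
        "gldm_glv": float((p * (ii - mu_i) ** 2).sum()),
        "gldm_dv": float((p * (jj - mu_j) ** 2).sum()),
        "gldm_de": float(-_xlog2(p).sum()),
        "gldm_lgle": float((p / ii**2).sum()),
        "gldm_hgle": float((p * ii**2).sum()),
        "gldm_sdlgle": float((p / (ii**2 * jj**2)).sum()),
        "gldm_sdhgle": float((p * ii**2 / jj**2).sum()),
        "gldm_ldlgle": float((p * jj**2 / ii**2).sum()),
        "gldm_ldhgle": float((p * ii**2 * jj**2).sum()),
    }


def ngtdm_features(roi: DiscretizedROI) -> dict[str, float]:
    """5 NGTDM features (26-neighborhood gray-tone differences)."""
    s, n = ngtdm_table(roi.levels, roi.ng)
    nv = n.sum()
    p = n / nv
    iv = np.arange(1, roi.ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ip, pp, sp = iv[present], p[present], s[present]

    ps_sum = float((p * s).sum())
    coarseness = min(1.0 / ps_sum, _COARSENESS_CAP) if ps_sum > 0 else _COARSENESS_CAP

    if ngp > 1:
        di = ip[:, None] - ip[None, :]
        contrast = float(
            (pp[:, None] * pp[None, :] * di**2).sum() / (ngp * (ngp - 1)) * (s.sum() / nv)
        )
        denom = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = ps_sum / denom if denom > 0 else 0.0
        complexity = float(
            (
                np.abs(di)
                * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
                / (pp[:, None] + pp[None, :])
            ).sum()
            / nv
        )
        s_tot = float(s.sum())
        strength = (
            float(((pp[:, None] + pp[None, :]) * di**2).sum()) / s_tot
            if s_tot > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }
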