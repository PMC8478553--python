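"""Single-phase and multiphase feature vector assembly.

``extract_single_phase`` produces the 105-feature vector of one phase
(18 first-order + 13 shape + 23 GLCM + 16 GLRLM + 16 GLSZM + 14 GLDM +
5 NGTDM); ``combine_phases`` concatenates the four phase vectors into
the 420-feature multiphase ("ALL-P") vector with phase-prefixed names.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .discretize import DEFAULT_BIN_WIDTH, discretize
from .firstorder import FIRST_ORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES,
    GLDM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    NGTDM_NAMES,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

PHASES = ("NCP", "CMP", "NP", "EP")

FEATURE_NAMES: tuple[str, ...] = (
    FIRST_ORDER_NAMES
    + SHAPE_NAMES
    + GLCM_NAMES
    + GLRLM_NAMES
    + GLSZM_NAMES
    + GLDM_NAMES
    + NGTDM_NAMES
)

FEATURE_CLASS_COUNTS = {
    "first_order": len(FIRST_ORDER_NAMES),
    "shape": len(SHAPE_NAMES),
    "glcm": len(GLCM_NAMES),
    "glrlm": len(GLRLM_NAMES),
    "glszm": len(GLSZM_NAMES),
    "gldm": len(GLDM_NAMES),
    "ngtdm": len(NGTDM_NAMES),
}


@dataclass(frozen=True)
class ExtractionConfig:
    """Settings of the feature extractor.

    bin_width : gray-level discretization width in HU.
    gldm_alpha : dependence tolerance (gray levels) for GLDM.
    """

    bin_width: float = DEFAULT_BIN_WIDTH
    gldm_alpha: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def extract_single_phase(
    voxels: np.ndarray,
    mask: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    config: ExtractionConfig | None = None,
) -> pd.Series:
    """Extract the 105-feature vector from one phase volume + mask.

    Returns a :class:`pandas.Series` indexed by feature name, in the
    fixed roster order.  Raises on empty masks or misaligned grids.
    """
    config = config or ExtractionConfig()
    voxels = np.asarray(voxels, dtype=float)
    mask_arr = np.asarray(mask) > 0.5
    if voxels.shape != mask_arr.shape:
        raise ValueError(
            f"volume shape {voxels.shape} != mask shape {mask_arr.shape}"
        )
    roi = discretize(voxels, mask_arr, bin_width=config.bin_width, spacing=spacing)
    out: dict[str, float] = {}
    out.update(first_order_features(roi))
    out.update(shape_features(mask_arr, spacing))
    out.update(glcm_features(roi))
    out.update(glrlm_features(roi))
    out.update(glszm_features(roi))
    out.update(gldm_features(roi, alpha=config.gldm_alpha))
    out.update(ngtdm_features(roi))
    vec = pd.Series(out, dtype=float).reindex(list(FEATURE_NAMES))
    if vec.isna().any():
        missing = vec.index[vec.isna()].tolist()
        raise RuntimeError(f"non-finite or missing features: {missing}")
    return vec


def combine_phases(vectors: dict[str, pd.Series]) -> pd.Series:
    """Concatenate one feature vector per phase into the 420-entry vector.

    Input is a mapping phase -> 105-feature Series; any iteration order
    is accepted, the output is always ordered NCP, CMP, NP, EP with
    names prefixed ``<phase>_``.
    """
    if set(vectors) != set(PHASES):
        raise ValueError(f"need exactly one vector per phase {PHASES}, got {sorted(vectors)}")
    parts = []
    for phase in PHASES:
        v = vectors[phase]
        if len(v) != len(FEATURE_NAMES):
            raise ValueError(f"phase {phase}: expected {len(FEATURE_NAMES)} features, got {len(v)}")
        parts.append(v.rename(lambda name: f"{phase}_{name}"))
    combined = pd.concat(parts)
    assert combined.index.is_unique
    return combined


def extract_feature_matrix(
    subjects,
    rater: int = 1,
    config: ExtractionConfig | None = None,
    phases=PHASES,
) -> dict[str, pd.DataFrame]:
    """Extract per-phase feature matrices for a cohort.

    Parameters
    ----------
    subjects : iterable of :class:`rcc_radiomics.cohort.Subject`.
    rater : which rater's mask to use (1 or 2).
    phases : phases to extract.

    Returns
    -------
    dict mapping phase -> DataFrame (subjects x 105 features, indexed by
    subject id).  The multiphase matrix can be formed with
    :func:`combine_phase_matrices`.
    """
    config = config or ExtractionConfig()
    rows: dict[str, dict[str, pd.Series]] = {ph: {} for ph in phases}
    for subj in subjects:
        mask = subj.masks[rater].voxels
        for ph in phases:
            vol = subj.volumes[ph]
            rows[ph][subj.id] = extract_single_phase(
                vol.voxels, mask, spacing=vol.spacing, config=config
            )
    return {ph: pd.DataFrame(rows[ph]).T for ph in phases}


def combine_phase_matrices(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Concatenate per-phase feature matrices into the ALL-P matrix."""
    if set(matrices) != set(PHASES):
        raise ValueError(f"need all phases {PHASES}")
    parts = [
        matrices[ph].rename(columns=lambda c: f"{ph}_{c}") for ph in PHASES
    ]
    out = pd.concat(parts, axis=1)
    if out.isna().any().any():
        raise ValueError("subject sets differ between phases")
    return out
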