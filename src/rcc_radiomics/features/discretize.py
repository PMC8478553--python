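"""Gray-level discretization of a masked CT region.

Texture matrices operate on integer gray levels rather than raw Hounsfield
units.  Levels are assigned with a fixed bin width anchored at the ROI
minimum::

    level(v) = floor((v - min_ROI) / bin_width) + 1

so the darkest voxel always maps to level 1 and the number of levels Ng
adapts to the ROI's dynamic range.  Anchoring at the ROI minimum makes the
level image — and hence every discretized texture feature — invariant to
adding a constant HU offset to the whole volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BIN_WIDTH = 25.0  # HU; conventional fixed-bin-width default


@dataclass(frozen=True)
class DiscretizedROI:
    """A discretized region of interest.

    Attributes
    ----------
    levels : 3D int array, same shape as the source volume; gray level
        1..Ng inside the mask and 0 outside.
    mask : 3D bool array of the ROI.
    values : 1D float array of the raw HU values of the masked voxels
        (in C scan order), kept for first-order statistics.
    ng : number of gray levels actually present (max level).
    bin_width : HU width of one gray level.
    spacing : per-axis voxel size in mm, array index order (z, y, x).
    """

    levels: np.ndarray
    mask: np.ndarray
    values: np.ndarray
    ng: int
    bin_width: float
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def level_histogram(self) -> np.ndarray:
        """Counts of masked voxels per gray level (index 0 -> level 1)."""
        return np.bincount(self.levels[self.mask] - 1, minlength=self.ng)

    def level_probabilities(self) -> np.ndarray:
        h = self.level_histogram()
        return h / h.sum()


def discretize(
    voxels: np.ndarray,
    mask: np.ndarray,
    bin_width: float = DEFAULT_BIN_WIDTH,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> DiscretizedROI:
    """Discretize the masked voxels of ``voxels`` into integer gray levels.

    Parameters
    ----------
    voxels : 3D array of attenuation values (HU).
    mask : 3D boolean (or 0/1) array aligned with ``voxels``.
    bin_width : gray-level bin width in HU; must be > 0.
    spacing : voxel size (mm) per axis, passed through for spatial features.
    """
    voxels = np.asarray(voxels, dtype=float)
    mask = np.asarray(mask) > 0.5
    if voxels.shape != mask.shape:
        raise ValueError(
            f"volume shape {voxels.shape} != mask shape {mask.shape}"
        )
    if voxels.ndim != 3:
        raise ValueError("expected a 3D volume")
    if not np.any(mask):
        raise ValueError("mask is empty")
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    values = voxels[mask]
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite voxel values inside the mask")

    levels = np.zeros(voxels.shape, dtype=np.int32)
    levels[mask] = np.floor((values - values.min()) / bin_width).astype(np.int32) + 1
    ng = int(levels.max())
    return DiscretizedROI(
        levels=levels,
        mask=mask,
        values=values,
        ng=ng,
        bin_width=float(bin_width),
        spacing=tuple(float(s) for s in spacing),
    )
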