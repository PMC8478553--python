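"""First-order (intensity histogram) features.

Eighteen statistics of the raw HU values inside the ROI.  Entropy and
uniformity are the only two that operate on the discretized gray levels;
everything else uses the continuous values.  Variance, skewness and
kurtosis are population (biased) moments, and kurtosis is *not*
excess-corrected, matching the conventional radiomics definitions.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

FIRST_ORDER_NAMES = (
    "fo_mean",
    "fo_median",
    "fo_minimum",
    "fo_maximum",
    "fo_range",
    "fo_variance",
    "fo_skewness",
    "fo_kurtosis",
    "fo_energy",
    "fo_total_energy",
    "fo_entropy",
    "fo_uniformity",
    "fo_mad",
    "fo_robust_mad",
    "fo_rms",
    "fo_p10",
    "fo_p90",
    "fo_iqr",
)


def first_order_features(roi: DiscretizedROI) -> dict[str, float]:
    """Return the 18 first-order features of ``roi`` as an ordered dict."""
    v = roi.values
    n = v.size
    mean = v.mean()
    centered = v - mean
    m2 = np.mean(centered**2)
    m3 = np.mean(centered**3)
    m4 = np.mean(centered**4)
    skewness = 0.0 if m2 == 0 else m3 / m2**1.5
    kurtosis = 0.0 if m2 == 0 else m4 / m2**2

    p = roi.level_probabilities()
    p = p[p > 0]
    entropy = float(-np.sum(p * np.log2(p)))
    uniformity = float(np.sum(p**2))

    p10, p25, p75, p90 = np.percentile(v, [10, 25, 75, 90])
    robust = v[(v >= p10) & (v <= p90)]
    robust_mad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    voxel_volume = float(np.prod(roi.spacing))
    energy = float(np.sum(v**2))

    return {
        "fo_mean": float(mean),
        "fo_median": float(np.median(v)),
        "fo_minimum": float(v.min()),
        "fo_maximum": float(v.max()),
        "fo_range": float(v.max() - v.min()),
        "fo_variance": float(m2),
        "fo_skewness": float(skewness),
        "fo_kurtosis": float(kurtosis),
        "fo_energy": energy,
        "fo_total_energy": voxel_volume * energy,
        "fo_entropy": entropy,
        "fo_uniformity": uniformity,
        "fo_mad": float(np.mean(np.abs(centered))),
        "fo_robust_mad": robust_mad,
        "fo_rms": float(np.sqrt(np.mean(v**2))),
        "fo_p10": float(p10),
        "fo_p90": float(p90),
        "fo_iqr": float(p75 - p25),
    }
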