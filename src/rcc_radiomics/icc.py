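"""Inter-rater reproducibility filtering via the intraclass correlation.

Features are extracted twice — once per rater's segmentation — and only
features whose two-rater ICC exceeds 0.80 are kept.  The ICC form is the
two-way random-effects, absolute-agreement, single-measurement
coefficient, ICC(2,1):

    ICC = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E) / n)

with n subjects, k = 2 raters, and MS_R / MS_C / MS_E the subject,
rater, and residual mean squares of the two-way ANOVA.  A consistency
variant, ICC(3,1) = (MS_R - MS_E)/(MS_R + (k-1) MS_E), is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_ICC_THRESHOLD = 0.80


@dataclass
class ICCResult:
    """Per-feature ICC values plus the estimation context."""

    table: pd.DataFrame  # columns: icc, retained
    model: str
    n_subjects: int
    k_raters: int = 2


def icc_two_rater(x1, x2, model: str = "agreement") -> float:
    """Two-rater single-measurement ICC of paired feature values.

    Parameters
    ----------
    x1, x2 : per-subject values from rater 1 and rater 2 (length n >= 3).
    model : ``"agreement"`` for ICC(2,1) (default) or ``"consistency"``
        for ICC(3,1).

    Returns NaN when the data carry no variance at all (the feature is
    then treated as *not* reproducible by :func:`filter_features`).
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be equal-length 1D arrays")
    n = x1.size
    if n < 3:
        raise ValueError("need at least 3 subjects for an ICC estimate")
    if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
        raise ValueError("non-finite feature values")

    data = np.stack([x1, x2], axis=1)  # n x k
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((subj_means - grand) ** 2).sum()
    ss_cols = n * ((rater_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if model == "agreement":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    elif model == "consistency":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown ICC model {model!r}")
    if denom <= 0 or ss_total == 0:
        return float("nan")
    return float((ms_r - ms_e) / denom)


def filter_features(
    matrix_r1: pd.DataFrame,
    matrix_r2: pd.DataFrame,
    threshold: float = DEFAULT_ICC_THRESHOLD,
    model: str = "agreement",
) -> tuple[list[str], ICCResult]:
    """Retain features whose inter-rater ICC strictly exceeds ``threshold``.

    Both matrices must hold the same subjects (rows) and features
    (columns).  NaN ICCs (zero-variance features) are never retained.
    """
    if list(matrix_r1.columns) != list(matrix_r2.columns):
        raise ValueError("feature rosters differ between raters")
    if list(matrix_r1.index) != list(matrix_r2.index):
        raise ValueError("subject sets differ between raters")
    iccs = {
        f: icc_two_rater(matrix_r1[f].to_numpy(), matrix_r2[f].to_numpy(), model)
        for f in matrix_r1.columns
    }
    table = pd.DataFrame({"icc": pd.Series(iccs)})
    table["retained"] = table["icc"] > threshold
    table.loc[table["icc"].isna(), "retained"] = False
    retained = table.index[table["retained"]].tolist()
    return retained, ICCResult(
        table=table, model=model, n_subjects=len(matrix_r1)
    )
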