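"""Bagged-LASSO stability selection.

The feature selector is an ensemble of LASSO "basic learners".  Each
learner runs many independent stratified 5-fold cross-validations; every
fold yields one L1-penalized linear fit (train 80% / validate 20%) whose
penalty is chosen on a small grid by validation mean-squared error.
Fits with validation R^2 above a retention threshold (default 0.8) are
kept, and a feature's *frequency* is the fraction of retained fits in
which its coefficient is nonzero.  Features with frequency at or above
the cutoff (default 0.2) are selected.

For a multiclass outcome, the outcome enters the LASSO as one-vs-rest
0/1 indicators: selection runs once per class and the union of the
per-class selected sets feeds the downstream one-vs-rest classifier.
A numeric outcome is regressed directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import lasso_path
from sklearn.model_selection import StratifiedKFold

DEFAULT_ALPHAS = (0.001, 0.003, 0.01, 0.03, 0.1, 0.3)


@dataclass
class SelectionConfig:
    """Stability-selection settings.

    ``n_learners`` x ``n_repeats`` full 5-fold CVs are run, i.e.
    ``n_learners * n_repeats * n_folds`` LASSO fits per outcome.  The
    study-scale configuration is 10 learners x 1000 repeats; scale
    ``n_repeats`` down for interactive use.
    """

    n_learners: int = 10
    n_repeats: int = 1000
    n_folds: int = 5
    r2_threshold: float = 0.8
    frequency_cutoff: float = 0.2
    alphas: tuple[float, ...] = DEFAULT_ALPHAS
    #: "1se": largest penalty within one standard error of the minimum
    #: validation MSE (parsimonious, stability-selection standard);
    #: "min": penalty minimizing validation MSE.
    penalty_rule: str = "1se"
    seed: int = 0

    def validate(self) -> None:
        if self.n_learners < 1 or self.n_repeats < 1:
            raise ValueError("n_learners and n_repeats must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0 <= self.frequency_cutoff <= 1:
            raise ValueError("frequency_cutoff must lie in [0, 1]")
        if self.r2_threshold > 1:
            raise ValueError("r2_threshold cannot exceed 1")


@dataclass
class SelectionResult:
    """Outcome of one stability-selection run."""

    frequency: pd.Series            # per-feature nonzero frequency in [0, 1]
    n_retained: int                 # fits with validation R^2 > threshold
    n_fits: int                     # completed fits
    selected: list[str]             # frequency >= cutoff (empty if none retained)
    r2_records: np.ndarray          # validation R^2 of every completed fit
    status: str = "ok"              # "ok" | "no-fit-retained"
    per_class: dict[str, "SelectionResult"] | None = None

    def report(self) -> pd.DataFrame:
        df = pd.DataFrame({"frequency": self.frequency})
        df["selected"] = df.index.isin(self.selected)
        return df.sort_values("frequency", ascending=False)


def fit_lasso_fold(X_train, y_train, X_val, y_val, alphas=DEFAULT_ALPHAS,
                   penalty_rule: str = "1se"):
    """One penalized fit on a train/validation split.

    Features are standardized on the training split only.  The penalty
    comes from a small grid scored by validation MSE: either the
    minimizer (``penalty_rule="min"``) or, by default, the largest
    penalty within one standard error of the minimum (``"1se"``), which
    keeps spurious noise coefficients out of the nonzero-frequency
    counts.  Returns ``(coefficients, validation_r2, alpha)``, or
    ``None`` when the split is degenerate (constant outcome on either
    side).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if np.ptp(y_train) == 0 or np.ptp(y_val) == 0:
        return None

    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Xt = (X_train - mu) / sd
    Xv = (X_val - mu) / sd
    y_mean = y_train.mean()

    alphas_sorted = np.sort(np.asarray(alphas, dtype=float))[::-1]
    _, coefs, _ = lasso_path(Xt, y_train - y_mean, alphas=alphas_sorted,
                             tol=1e-10, max_iter=10000)
    preds = Xv @ coefs + y_mean  # (n_val, n_alphas)
    errs = (preds - y_val[:, None]) ** 2
    mse = errs.mean(axis=0)
    best = int(np.argmin(mse))
    if penalty_rule == "1se":
        se = errs[:, best].std(ddof=1) / np.sqrt(len(y_val)) if len(y_val) > 1 else 0.0
        # alphas are descending, so the first qualifying index is the
        # largest penalty within one SE of the minimum
        best = int(np.flatnonzero(mse <= mse[best] + se)[0])
    elif penalty_rule != "min":
        raise ValueError(f"unknown penalty_rule {penalty_rule!r}")
    coef = coefs[:, best]
    ss_res = float(((y_val - preds[:, best]) ** 2).sum())
    ss_tot = float(((y_val - y_val.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    return coef, r2, float(alphas_sorted[best])


def _run_single_outcome(
    X: pd.DataFrame,
    y01: np.ndarray,
    stratify: np.ndarray,
    cfg: SelectionConfig,
    seed_seq: np.random.SeedSequence,
) -> SelectionResult:
    nonzero_counts = np.zeros(X.shape[1], dtype=np.int64)
    r2s: list[float] = []
    n_retained = 0
    n_fits = 0
    Xv = X.to_numpy(dtype=float)
    learner_seqs = seed_seq.spawn(cfg.n_learners)
    for learner_seq in learner_seqs:
        rng = np.random.default_rng(learner_seq)
        for _ in range(cfg.n_repeats):
            rs = int(rng.integers(0, 2**31))
            skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=rs)
            for tr, va in skf.split(Xv, stratify):
                res = fit_lasso_fold(Xv[tr], y01[tr], Xv[va], y01[va],
                                     cfg.alphas, cfg.penalty_rule)
                if res is None:
                    continue
                coef, r2, _ = res
                n_fits += 1
                r2s.append(r2)
                if r2 > cfg.r2_threshold:
                    n_retained += 1
                    nonzero_counts += coef != 0
    if n_retained > 0:
        freq = pd.Series(nonzero_counts / n_retained, index=X.columns)
        selected = freq.index[freq >= cfg.frequency_cutoff].tolist()
        status = "ok"
    else:
        freq = pd.Series(np.zeros(X.shape[1]), index=X.columns)
        selected = []
        status = "no-fit-retained"
        warnings.warn(
            "stability selection retained no fit (validation R^2 never "
            f"exceeded {cfg.r2_threshold}); empty selection returned",
            stacklevel=2,
        )
    return SelectionResult(
        frequency=freq,
        n_retained=n_retained,
        n_fits=n_fits,
        selected=selected,
        r2_records=np.asarray(r2s),
        status=status,
    )


def run_stability_selection(
    X: pd.DataFrame, y, cfg: SelectionConfig | None = None
) -> SelectionResult:
    """Run ensemble bagged-LASSO selection on a feature matrix.

    Parameters
    ----------
    X : subjects x features DataFrame.
    y : outcome — class labels (categorical; one-vs-rest indicator
        regressions are run per class and their selections unioned) or a
        numeric vector (single regression).
    cfg : :class:`SelectionConfig`; ``cfg.seed`` fixes the result.

    Notes
    -----
    Cross-validation shuffles are stratified by the *full* label vector,
    so the cohort's class imbalance is preserved in every fold even for
    the per-class indicator runs.
    """
    cfg = cfg or SelectionConfig()
    cfg.validate()
    y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("X and y length mismatch")
    if 2 * cfg.n_folds > len(X):
        raise ValueError("need at least 2 subjects per fold")
    root = np.random.SeedSequence(cfg.seed)

    if np.issubdtype(y.dtype, np.number) and len(np.unique(y)) > 2:
        return _run_single_outcome(X, y.astype(float), y > np.median(y), cfg, root)

    classes = [c for c in pd.unique(y)]
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    canonical = ["ccRCC", "pRCC", "cRCC"]
    classes = sorted(classes, key=lambda c: (canonical.index(c) if c in canonical else 99, str(c)))

    if len(classes) == 2:
        # a binary task is a single indicator regression (the two
        # indicators share R^2 and the nonzero-coefficient pattern)
        y01 = (y == classes[-1]).astype(float)
        return _run_single_outcome(X, y01, y, cfg, root)

    class_seqs = root.spawn(len(classes))
    per_class: dict[str, SelectionResult] = {}
    for cls, seq in zip(classes, class_seqs):
        y01 = (y == cls).astype(float)
        per_class[str(cls)] = _run_single_outcome(X, y01, y, cfg, seq)

    freq = pd.concat([r.frequency for r in per_class.values()], axis=1).max(axis=1)
    selected = sorted(
        set().union(*(r.selected for r in per_class.values())),
        key=list(X.columns).index,
    )
    n_fits = sum(r.n_fits for r in per_class.values())
    n_retained = sum(r.n_retained for r in per_class.values())
    status = "ok" if any(r.status == "ok" for r in per_class.values()) else "no-fit-retained"
    return SelectionResult(
        frequency=freq,
        n_retained=n_retained,
        n_fits=n_fits,
        selected=selected,
        r2_records=np.concatenate([r.r2_records for r in per_class.values()])
        if per_class
        else np.empty(0),
        status=status,
        per_class=per_class,
    )
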