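"""Subtype classifiers: one-vs-rest logistic models and the clinical control.

The final predictor for each phase (NCP/CMP/NP/EP/ALL-P) is a
one-vs-rest (OvR) logistic model over the stability-selected features:
one binary logistic fit per class, prediction by the highest class
probability, ties broken toward the more prevalent class.  Performance
is assessed by repeated stratified 5-fold cross-validation; every
subject is scored exactly once per repeat, as a validation-fold member.

The traditional control model applies the same OvR machinery to clinical
covariates that pass univariate screening (Kruskal-Wallis for continuous
variables, chi-square for categorical ones, p < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

CLASS_ORDER = ("ccRCC", "pRCC", "cRCC")


@dataclass
class OvRModel:
    """One-vs-rest logistic classifier with internal standardization."""

    classes: tuple[str, ...]
    feature_names: list[str]
    coefs: dict[str, np.ndarray]        # per class: (p,) coefficients
    intercepts: dict[str, float]
    mu: np.ndarray
    sd: np.ndarray
    class_counts: dict[str, int]
    ridge_fallback: dict[str, bool] = field(default_factory=dict)

    def scores(self, X) -> pd.DataFrame:
        """Per-class positive probabilities, columns in class order."""
        X = np.asarray(X, dtype=float)
        Xs = (X - self.mu) / self.sd
        out = {}
        for c in self.classes:
            z = np.clip(Xs @ self.coefs[c] + self.intercepts[c], -700, 700)
            out[c] = 1.0 / (1.0 + np.exp(-z))
        return pd.DataFrame(out)

    def predict(self, X) -> np.ndarray:
        """Argmax prediction; exact ties go to the more prevalent class."""
        s = self.scores(X)
        # stable tie-break: sort columns by descending training prevalence,
        # argmax picks the first of a tied group
        order = sorted(self.classes, key=lambda c: -self.class_counts[c])
        vals = s[order].to_numpy()
        idx = np.argmax(vals, axis=1)
        return np.asarray([order[i] for i in idx])

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "feature_names": self.feature_names,
            "coefs": {c: self.coefs[c].tolist() for c in self.classes},
            "intercepts": self.intercepts,
            "mu": self.mu.tolist(),
            "sd": self.sd.tolist(),
            "class_counts": self.class_counts,
            "ridge_fallback": self.ridge_fallback,
        }


def build_binary_task(y, positive_class: str) -> np.ndarray:
    """0/1 labels for a one-subtype-vs-rest task."""
    y = np.asarray(y)
    if positive_class not in y:
        raise ValueError(f"class {positive_class!r} absent from labels")
    return (y == positive_class).astype(int)


def _fit_binary_logistic(Xs, y01):
    """Unpenalized ML logistic fit with a tiny-ridge fallback.

    Quasi-separated folds (easy with 5 pRCC cases per fold) make the
    unpenalized likelihood unbounded; the fallback refits with a weak L2
    penalty and flags it.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                     max_iter=500, tol=1e-8)
            clf.fit(Xs, y01)
            return clf.coef_[0], float(clf.intercept_[0]), False
        except ConvergenceWarning:
            pass
    clf = LogisticRegression(C=1e3, solver="lbfgs", max_iter=2000, tol=1e-8)
    clf.fit(Xs, y01)
    return clf.coef_[0], float(clf.intercept_[0]), True


def fit_ovr_logistic(X, y, classes=None) -> OvRModel:
    """Fit the OvR logistic model on selected features.

    ``X`` may be a DataFrame (column names kept) or array.  Every class
    in ``classes`` must appear in ``y``.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = [f"x{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y)
    if classes is None:
        present = set(y)
        classes = tuple(c for c in CLASS_ORDER if c in present) or tuple(
            sorted(present, key=str)
        )
    for c in classes:
        if c not in y:
            raise ValueError(f"class {c!r} absent from training data")

    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xv - mu) / sd

    coefs, intercepts, fallback = {}, {}, {}
    for c in classes:
        y01 = (y == c).astype(int)
        coefs[c], intercepts[c], fallback[c] = _fit_binary_logistic(Xs, y01)
    counts = {c: int((y == c).sum()) for c in classes}
    return OvRModel(
        classes=tuple(classes), feature_names=feature_names, coefs=coefs,
        intercepts=intercepts, mu=mu, sd=sd, class_counts=counts,
        ridge_fallback=fallback,
    )


def repeated_stratified_cv(
    X, y, k: int = 5, repeats: int = 50, seed: int = 0, classes=None
):
    """Repeated stratified k-fold CV of the OvR logistic model.

    Returns ``(predictions, repeat_metrics)``:

    * ``predictions`` — DataFrame with one row per subject per repeat
      (columns: subject, repeat, fold, truth, predicted, one score column
      per class);
    * ``repeat_metrics`` — DataFrame with per-repeat multiclass accuracy.
    """
    if isinstance(X, pd.DataFrame):
        subject_ids = list(X.index)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        subject_ids = list(range(len(Xv)))
    y = np.asarray(y)
    binc = pd.Series(y).value_counts()
    if (binc < k).any():
        raise ValueError(
            f"cannot stratify: class counts {binc.to_dict()} below k={k}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    accs = []
    for rep in range(repeats):
        rs = int(rng.integers(0, 2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        pred_all = np.empty(len(y), dtype=object)
        for fold, (tr, va) in enumerate(skf.split(Xv, y)):
            model = fit_ovr_logistic(Xv[tr], y[tr], classes=classes)
            sc = model.scores(Xv[va])
            pr = model.predict(Xv[va])
            pred_all[va] = pr
            for j, i in enumerate(va):
                row = {
                    "subject": subject_ids[i],
                    "repeat": rep,
                    "fold": fold,
                    "truth": y[i],
                    "predicted": pr[j],
                }
                row.update({f"score_{c}": sc.iloc[j][c] for c in sc.columns})
                rows.append(row)
        accs.append({"repeat": rep, "accuracy": float((pred_all == y).mean())})
    return pd.DataFrame(rows), pd.DataFrame(accs)


def repeated_binary_cv(X, y01, k: int = 5, repeats: int = 50, seed: int = 0):
    """Repeated stratified k-fold CV of a single binary logistic model.

    Returns ``(mean_scores, repeat_metrics)`` where ``mean_scores`` is
    the per-subject validation score averaged over repeats (usable for
    paired ROC comparisons) and ``repeat_metrics`` holds per-repeat AUC
    and accuracy at the 0.5 threshold.
    """
    from .metrics import roc_auc

    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    y01 = np.asarray(y01).astype(int)
    if min((y01 == 1).sum(), (y01 == 0).sum()) < k:
        raise ValueError("cannot stratify: a class has fewer members than k")
    rng = np.random.default_rng(seed)
    score_sum = np.zeros(len(y01))
    recs = []
    for rep in range(repeats):
        rs = int(rng.integers(0, 2**31))
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        scores = np.empty(len(y01))
        for tr, va in skf.split(Xv, y01):
            mu = Xv[tr].mean(axis=0)
            sd = Xv[tr].std(axis=0)
            sd[sd == 0] = 1.0
            coef, intercept, _ = _fit_binary_logistic((Xv[tr] - mu) / sd, y01[tr])
            z = np.clip((Xv[va] - mu) / sd @ coef + intercept, -700, 700)
            scores[va] = 1.0 / (1.0 + np.exp(-z))
        score_sum += scores
        recs.append(
            {
                "repeat": rep,
                "auc": roc_auc(scores, y01),
                "accuracy": float(((scores >= 0.5).astype(int) == y01).mean()),
            }
        )
    return score_sum / repeats, pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# traditional clinical model


@dataclass
class TraditionalModel:
    """Clinical control model: screened covariates + OvR logistic."""

    screened: list[str]
    screen_table: pd.DataFrame
    model: OvRModel
    design_columns: list[str]


def screen_clinical_variables(
    table: pd.DataFrame, y, alpha: float = 0.05
) -> pd.DataFrame:
    """Univariate screen of clinical covariates across the 3 subtypes.

    Continuous columns get a Kruskal-Wallis H test, categorical columns
    a chi-square test on the subtype contingency table (Pearson, no
    continuity correction).  Returns a DataFrame (variable, kind, p,
    kept, note); variables with empty contingency rows/columns are
    flagged and excluded.
    """
    y = np.asarray(y)
    records = []
    for col in table.columns:
        s = table[col]
        note = ""
        if pd.api.types.is_numeric_dtype(s):
            kind = "continuous"
            groups = [s.to_numpy()[y == g] for g in pd.unique(y)]
            if all(np.ptp(g) == 0 for g in groups if len(g)) and len(
                np.unique(s)
            ) == 1:
                p = 1.0
                note = "constant"
            else:
                p = float(stats.kruskal(*groups).pvalue)
        else:
            kind = "categorical"
            ct = pd.crosstab(s, y)
            if ct.shape[0] < 2 or (ct.sum(axis=1) == 0).any():
                p, note = np.nan, "degenerate-contingency"
            else:
                res = stats.chi2_contingency(ct.to_numpy(), correction=False)
                p = float(res.pvalue)
                if (res.expected_freq == 0).any():
                    note = "zero-expected-cell"
        kept = bool(p < alpha) if np.isfinite(p) and not note.startswith("degenerate") else False
        if note in ("degenerate-contingency", "zero-expected-cell") and note:
            kept = False
            warnings.warn(f"variable {col!r} excluded from screen: {note}",
                          stacklevel=2)
        records.append({"variable": col, "kind": kind, "p": p, "kept": kept,
                        "note": note})
    return pd.DataFrame(records).set_index("variable")


def clinical_design_matrix(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Numeric design matrix: dummies for categoricals, raw numerics."""
    parts = []
    for v in variables:
        s = table[v]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float).to_frame())
        else:
            parts.append(pd.get_dummies(s, prefix=v, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def fit_traditional(
    table: pd.DataFrame, y, alpha: float = 0.05, classes=None
) -> TraditionalModel:
    """Screen clinical covariates and fit the OvR logistic control model."""
    screen = screen_clinical_variables(table, y, alpha=alpha)
    screened = screen.index[screen["kept"]].tolist()
    if not screened:
        raise ValueError("no clinical variable passed the p < %.2f screen" % alpha)
    design = clinical_design_matrix(table, screened)
    model = fit_ovr_logistic(design, y, classes=classes)
    return TraditionalModel(
        screened=screened,
        screen_table=screen,
        model=model,
        design_columns=list(design.columns),
    )
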