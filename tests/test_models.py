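"""OvR logistic models, repeated stratified CV, and the clinical control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rcc_radiomics import (
    build_binary_task,
    fit_ovr_logistic,
    fit_traditional,
    repeated_binary_cv,
    repeated_stratified_cv,
    screen_clinical_variables,
)


def _three_clusters(rng, n_per=20, sep=6.0):
    y = np.repeat(["ccRCC", "pRCC", "cRCC"], n_per)
    centers = {"ccRCC": (0, 0), "pRCC": (sep, 0), "cRCC": (0, sep)}
    X = np.stack([rng.normal(centers[c], 0.5) for c in y])
    return X, y


class TestOvR:
    def test_separable_clusters_training_accuracy_one(self, rng):
        X, y = _three_clusters(rng)
        model = fit_ovr_logistic(X, y)
        assert (model.predict(X) == y).all()

    def test_row_permutation_invariance(self, rng):
        X, y = _three_clusters(rng, n_per=15)
        perm = rng.permutation(len(y))
        a = fit_ovr_logistic(X, y)
        b = fit_ovr_logistic(X[perm], y[perm])
        for c in a.classes:
            np.testing.assert_allclose(a.coefs[c], b.coefs[c], rtol=1e-5, atol=1e-6)

    def test_missing_class_named_in_error(self, rng):
        X, y = _three_clusters(rng, n_per=10)
        keep = y != "cRCC"
        with pytest.raises(ValueError, match="cRCC"):
            fit_ovr_logistic(X[keep], y[keep], classes=("ccRCC", "pRCC", "cRCC"))

    def test_logodds_coefficient_recovery(self):
        """At n=500 the fitted slope recovers the generating log-odds
        coefficient to within its standard error.  A single replicate is
        only ~68% likely to land inside one SE even for a perfect
        estimator, so the check uses the median absolute error over 15
        replicates (median |error| of a calibrated estimator is ~0.67
        SE, comfortably below 1 SE)."""
        beta, n = 1.2, 500
        errors, ses = [], []
        for rep in range(15):
            rng = np.random.default_rng(1000 + rep)
            x = rng.normal(size=(n, 1))
            p = 1 / (1 + np.exp(-(0.5 + beta * x[:, 0])))
            y = np.where(rng.random(n) < p, "ccRCC", "pRCC")
            model = fit_ovr_logistic(x, y)
            slope = model.coefs["ccRCC"][0] / model.sd[0]  # undo standardization
            # Fisher-information standard error at the fitted model
            z = model.intercepts["ccRCC"] + model.coefs["ccRCC"][0] * (
                (x[:, 0] - model.mu[0]) / model.sd[0]
            )
            w = 1 / (1 + np.exp(-z))
            design = np.column_stack([np.ones(n), x[:, 0]])
            info = design.T @ (design * (w * (1 - w))[:, None])
            ses.append(np.sqrt(np.linalg.inv(info)[1, 1]))
            errors.append(abs(slope - beta))
        assert np.median(errors) <= np.median(ses)


class TestBinaryTask:
    def test_basic_encoding(self):
        y = np.array(["ccRCC", "pRCC", "cRCC"])
        assert build_binary_task(y, "ccRCC").tolist() == [1, 0, 0]

    def test_imbalanced_counts(self):
        y = np.array(["ccRCC"] * 209 + ["pRCC"] * 25 + ["cRCC"] * 29)
        t = build_binary_task(y, "pRCC")
        assert t.sum() == 25 and (1 - t).sum() == 238

    def test_exclusive_positives(self):
        y = np.array(["ccRCC", "pRCC", "cRCC", "pRCC"])
        total = build_binary_task(y, "pRCC") + build_binary_task(y, "cRCC")
        assert total.max() <= 1

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            build_binary_task(np.array(["ccRCC"]), "oncocytoma")


class TestRepeatedCV:
    def test_each_subject_validated_once_per_repeat(self, rng):
        X, y = _three_clusters(rng, n_per=10)
        preds, _ = repeated_stratified_cv(X, y, k=5, repeats=3, seed=0)
        counts = preds.groupby(["repeat", "subject"]).size()
        assert (counts == 1).all()
        assert preds.groupby("repeat").size().eq(30).all()

    def test_fold_class_balance(self, rng):
        X, y = _three_clusters(rng, n_per=15)
        preds, _ = repeated_stratified_cv(X, y, k=5, repeats=2, seed=1)
        per_fold = preds.groupby(["repeat", "fold"])["truth"].value_counts()
        # 15 per class over 5 folds -> exactly 3 of each class per fold
        assert (per_fold == 3).all()

    def test_seed_determinism(self, rng):
        X, y = _three_clusters(rng, n_per=10)
        a, am = repeated_stratified_cv(X, y, repeats=2, seed=7)
        b, bm = repeated_stratified_cv(X, y, repeats=2, seed=7)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(am, bm)

    def test_class_below_k_rejected(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array(["a"] * 9 + ["b"] * 3)
        with pytest.raises(ValueError, match="stratify"):
            repeated_stratified_cv(X, y, k=5, repeats=1, seed=0)

    def test_null_scores_give_chance_auc(self):
        """With labels carrying no signal, CV AUC averages ~0.5.  Any
        single finite dataset has accidental feature-label correlation,
        so the mean is taken over fresh datasets as well as repeats."""
        y01 = np.r_[np.ones(20, int), np.zeros(40, int)]
        aucs = []
        for ds in range(40):
            X = np.random.default_rng(500 + ds).normal(size=(60, 3))
            _, recs = repeated_binary_cv(X, y01, repeats=5, seed=ds)
            aucs.append(recs["auc"].mean())
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)


class TestScreening:
    def test_constant_variable_excluded(self):
        y = np.repeat(["ccRCC", "pRCC", "cRCC"], 10)
        table = pd.DataFrame({"flat": np.ones(30), "age": np.arange(30.0)})
        res = screen_clinical_variables(table, y)
        assert not res.loc["flat", "kept"]
        assert res.loc["flat", "p"] > 0.9

    def test_published_sex_contingency_kept(self):
        """The published cohort's sex-by-subtype table screens in
        (chi-square p ~ 0.025 < 0.05)."""
        y = np.array(["ccRCC"] * 207 + ["pRCC"] * 25 + ["cRCC"] * 29)
        sex = np.array(
            ["male"] * 136 + ["female"] * 71
            + ["male"] * 18 + ["female"] * 7
            + ["male"] * 12 + ["female"] * 17
        )
        res = screen_clinical_variables(pd.DataFrame({"sex": sex}), y)
        assert res.loc["sex", "kept"]
        assert res.loc["sex", "p"] == pytest.approx(0.0255, abs=0.002)

    def test_kruskal_with_ties_matches_rank_oracle(self):
        vals = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 5.0, 5.0, 7.0, 8.0])
        y = np.array(["a", "a", "a", "b", "b", "b", "c", "c", "c"])
        res = screen_clinical_variables(pd.DataFrame({"v": vals}), y)
        # hand computation: tie-corrected Kruskal-Wallis H
        ranks = stats.rankdata(vals)
        n = len(vals)
        h = 12 / (n * (n + 1)) * sum(
            len(ranks[y == g]) * ranks[y == g].mean() ** 2 for g in "abc"
        ) - 3 * (n + 1)
        _, counts = np.unique(vals, return_counts=True)
        h /= 1 - ((counts**3 - counts).sum()) / (n**3 - n)
        assert res.loc["v", "p"] == pytest.approx(stats.chi2.sf(h, 2), abs=1e-12)


class TestTraditional:
    def _table(self, rng, n_per=40, planted=True):
        y = np.repeat(["ccRCC", "pRCC", "cRCC"], n_per)
        att = {"ccRCC": 105.0, "pRCC": 54.0, "cRCC": 85.0}
        table = pd.DataFrame(
            {
                "att_cmp": [
                    (att[c] if planted else 80.0) + rng.normal(0, 8) for c in y
                ],
                "noise_num": rng.normal(size=3 * n_per),
                "noise_cat": rng.choice(["u", "v"], 3 * n_per),
            }
        )
        return table, y

    def test_planted_attenuation_survives_and_dominates(self, rng):
        table, y = self._table(rng)
        trad = fit_traditional(table, y)
        assert trad.screened == ["att_cmp"]
        coef_mag = {c: np.abs(trad.model.coefs[c]).max() for c in trad.model.classes}
        assert all(v > 0 for v in coef_mag.values())

    def test_pure_noise_accuracy_near_majority(self, rng):
        y = np.array(["ccRCC"] * 40 + ["pRCC"] * 10 + ["cRCC"] * 10)
        X = rng.normal(size=(60, 3))
        _, accs = repeated_stratified_cv(X, y, repeats=30, seed=3)
        assert accs["accuracy"].mean() == pytest.approx(40 / 60, abs=0.12)

    def test_refit_deterministic(self, rng):
        table, y = self._table(rng, n_per=25)
        a = fit_traditional(table, y)
        b = fit_traditional(table, y)
        for c in a.model.classes:
            np.testing.assert_array_equal(a.model.coefs[c], b.model.coefs[c])

    def test_all_noise_raises_when_nothing_screens_in(self, rng):
        table, y = self._table(rng, planted=False)
        table = table.drop(columns=["att_cmp"])
        with pytest.raises(ValueError):
            fit_traditional(table, y)
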