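"""Standardization, LDA/PCA, cross-validation, effect sizes, subset search."""
import numpy as np
import pandas as pd
import pytest

from cnephys.classify import (
    ClassificationError,
    Imputer,
    LDAModel,
    combination_search,
    confusion,
    cross_validate,
    fit_lda,
    fit_pca,
    impute_missing,
    measure_r2,
    standardize,
)
from cnephys.tables import MEASURES, FeatureTable, feature_table_from_rows


def toy_table(n_per_class=20, n_classes=3, sep=4.0, seed=0, missing=()):
    """Gaussian clusters along the first few measures; rest is noise."""
    rng = np.random.default_rng(seed)
    classes = ["bushy", "pyramidal", "cartwheel", "planar_multipolar",
               "radiate_multipolar", "tuberculoventral"][:n_classes]
    rows = []
    for k, cls in enumerate(classes):
        for i in range(n_per_class):
            row = {"cell_id": f"{cls}_{i}", "class_label": cls}
            for j, m in enumerate(MEASURES):
                center = sep * k if j < 4 else 0.0
                row[m] = center + rng.normal()
            rows.append(row)
    t = feature_table_from_rows(rows)
    for cell, m in missing:
        t.values.loc[cell, m] = np.nan
    return t


class TestStandardize:
    def test_hand_zscores_sample_sd(self):
        """Column {1,2,3} with the repo-wide sample-SD convention -> {-1,0,1}."""
        t = toy_table(n_per_class=1, n_classes=3)
        t.values.loc[:, "RMP"] = [1.0, 2.0, 3.0]
        std, sc = standardize(t)
        np.testing.assert_allclose(std.values["RMP"], [-1.0, 0.0, 1.0], atol=1e-12)
        assert sc.sds["RMP"] == pytest.approx(1.0)

    def test_idempotent_on_zscores(self):
        std1, _ = standardize(toy_table())
        std2, _ = standardize(std1)
        np.testing.assert_allclose(std1.values, std2.values, atol=1e-12)

    def test_constant_column_error_names_column(self):
        t = toy_table()
        t.values.loc[:, "rebound"] = 2.0
        with pytest.raises(ClassificationError, match="rebound"):
            standardize(t)

    def test_missing_values_left_missing(self):
        t = toy_table(missing=[("bushy_0", "CV")])
        std, _ = standardize(t)
        assert np.isnan(std.values.loc["bushy_0", "CV"])


class TestImpute:
    def test_column_median_fill(self):
        t = toy_table(missing=[("bushy_0", "CV")])
        filled, imp = impute_missing(t, "column-median")
        others = t.values["CV"].drop("bushy_0")
        assert filled.values.loc["bushy_0", "CV"] == pytest.approx(others.median())
        assert imp.mask.loc["bushy_0", "CV"]
        assert not filled.values.isna().any().any()

    def test_drop_cell_policy(self):
        t = toy_table(missing=[("bushy_0", "CV")])
        filled, _ = impute_missing(t, "drop-cell")
        assert "bushy_0" not in filled.values.index
        assert len(filled) == len(t) - 1

    def test_unknown_policy_rejected(self):
        with pytest.raises(ClassificationError, match="policy"):
            impute_missing(toy_table(), "mean-of-everything")


class TestLDA:
    def test_two_class_direction_matches_fisher_closed_form(self):
        """LDA axis equals Sw^-1 (mu1 - mu0) up to scale."""
        rng = np.random.default_rng(5)
        n = 150
        cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        L = np.linalg.cholesky(cov)
        X0 = rng.standard_normal((n, 2)) @ L.T
        X1 = rng.standard_normal((n, 2)) @ L.T + [2.0, 1.0]
        X = np.vstack([X0, X1])
        y = np.array(["a"] * n + ["b"] * n)
        model = LDAModel().fit(X, y)
        Sw = (X0 - X0.mean(0)).T @ (X0 - X0.mean(0)) + (X1 - X1.mean(0)).T @ (X1 - X1.mean(0))
        fisher = np.linalg.solve(Sw, X1.mean(0) - X0.mean(0))
        w = model.scalings_[:, 0]
        cos = abs(w @ fisher) / (np.linalg.norm(w) * np.linalg.norm(fisher))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_six_classes_give_five_components(self, cohort_table):
        model, result = fit_lda(cohort_table)
        assert model.n_components == 5
        ve = result.variance_explained
        assert ve.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ve) <= 1e-12)
        assert np.all(ve >= 0)

    def test_matches_sklearn_eigen_solver(self, cohort_table):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        from cnephys.classify import _prepared

        X, y, _, _ = _prepared(cohort_table)
        ours = LDAModel().fit(X, y)
        ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, y)
        np.testing.assert_allclose(
            ours.variance_explained_, ref.explained_variance_ratio_, atol=1e-6
        )
        # same discriminant subspace: projections agree up to a rotation/sign,
        # checked via principal angles between the two scaling subspaces
        q1, _ = np.linalg.qr(ours.scalings_)
        q2, _ = np.linalg.qr(ref.scalings_[:, :5])
        sv = np.linalg.svd(q1.T @ q2, compute_uv=False)
        np.testing.assert_allclose(sv, 1.0, atol=1e-6)

    def test_zero_within_class_variance_separates_perfectly(self):
        rows = []
        for k, cls in enumerate(["bushy", "pyramidal", "cartwheel"]):
            for i in range(12):
                row = {"cell_id": f"{cls}_{i}", "class_label": cls}
                row.update({m: float(k * (j + 1)) for j, m in enumerate(MEASURES)})
                rows.append(row)
        X = pd.DataFrame([r for r in rows]).set_index("cell_id")[list(MEASURES)].to_numpy()
        y = np.array([r["class_label"] for r in rows])
        model = LDAModel().fit(X, y)  # singular Sw -> shrinkage fallback
        assert model.shrinkage_used_
        assert (model.predict(X) == y).all()

    def test_fewer_than_two_classes_rejected(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ClassificationError, match="2 classes"):
            LDAModel().fit(X, np.array(["a"] * 10))


class TestPCA:
    def test_one_latent_factor_concentrates_variance(self):
        """All measures driven by one latent factor -> PC1 carries ~everything
        (after standardization only correlation structure matters)."""
        rng = np.random.default_rng(2)
        t = toy_table(n_per_class=30, n_classes=2)
        latent = rng.standard_normal(len(t))
        for j, m in enumerate(MEASURES):
            t.values.loc[:, m] = (j + 1) * latent + 1e-3 * rng.standard_normal(len(t))
        model, result = fit_pca(t)
        assert result.variance_explained[0] > 0.99

    def test_isotropic_data_spreads_variance_evenly(self):
        t = toy_table(n_per_class=400, n_classes=2, sep=0.0, seed=9)
        model, result = fit_pca(t)
        assert result.variance_explained[0] < 2.5 / 12

    def test_nearest_centroid_prediction_on_separated_classes(self):
        t = toy_table(sep=8.0)
        model, result = fit_pca(t)
        assert np.trace(result.confusion.to_numpy()) == pytest.approx(3.0, abs=0.1)


class TestCrossValidation:
    def test_perfectly_separated_classes_score_one(self):
        t = toy_table(sep=12.0, n_per_class=20)
        mean, sd = cross_validate(t, k=10, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_permuted_labels_score_near_chance(self):
        t = toy_table(n_per_class=20, n_classes=6, sep=5.0, seed=1)
        rng = np.random.default_rng(7)
        t.labels[:] = rng.permutation(t.labels.to_numpy())
        mean, _ = cross_validate(t, k=10, seed=3)
        assert 0.03 < mean < 0.35  # 1/6 within Monte-Carlo slack

    def test_same_seed_reproduces_folds_exactly(self, cohort_table):
        a = cross_validate(cohort_table, k=10, seed=5, return_predictions=True)
        b = cross_validate(cohort_table, k=10, seed=5, return_predictions=True)
        assert a[0] == b[0] and a[1] == b[1]
        assert (a[2] == b[2]).all()

    def test_affine_rescaling_of_a_column_is_absorbed(self, cohort_table):
        mean0, _ = cross_validate(cohort_table, k=10, seed=2)
        t = cohort_table.copy()
        t.values.loc[:, "R_in"] = t.values["R_in"] * 3.0 + 7.0
        mean1, _ = cross_validate(t, k=10, seed=2)
        assert mean0 == pytest.approx(mean1, abs=1e-12)

    def test_class_smaller_than_k_rejected(self):
        t = toy_table(n_per_class=5, n_classes=3)
        with pytest.raises(ClassificationError, match="smaller than k"):
            cross_validate(t, k=10)

    def test_pure_noise_extra_measure_barely_moves_accuracy(self, cohort_table):
        """A 13th uninformative measure changes CV accuracy by < 0.05."""
        from sklearn.model_selection import StratifiedKFold

        from cnephys.classify import _prepared

        X, y, _, _ = _prepared(cohort_table)
        rng = np.random.default_rng(0)
        X13 = np.hstack([X, rng.standard_normal((X.shape[0], 1))])
        accs = {}
        for name, mat in (("base", X), ("plus_noise", X13)):
            skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=4)
            acc = []
            for tr, te in skf.split(mat, y):
                model = LDAModel().fit(mat[tr], y[tr])
                acc.append(np.mean(model.predict(mat[te]) == y[te]))
            accs[name] = np.mean(acc)
        assert abs(accs["base"] - accs["plus_noise"]) < 0.05


class TestConfusion:
    def test_perfect_classifier_identity(self):
        y = np.array(["a", "a", "b", "b", "c"])
        c = confusion(y, y, classes=["a", "b", "c"])
        np.testing.assert_allclose(c.to_numpy(), np.eye(3))

    def test_rows_sum_to_one(self, cohort_table):
        mean, sd, oof = cross_validate(cohort_table, k=10, seed=0, return_predictions=True)
        c = confusion(cohort_table.labels.to_numpy(), oof.to_numpy(),
                      classes=sorted(cohort_table.labels.unique()))
        np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-9)

    def test_planted_swaps_appear_off_diagonal(self):
        """25% planar<->radiate swaps show up as ~0.25 off-diagonal."""
        rng = np.random.default_rng(0)
        y = np.repeat(["planar_multipolar", "radiate_multipolar", "bushy"], 100)
        pred = y.copy()
        for cls, other in [("planar_multipolar", "radiate_multipolar"),
                           ("radiate_multipolar", "planar_multipolar")]:
            idx = np.flatnonzero(y == cls)
            pred[rng.choice(idx, size=25, replace=False)] = other
        c = confusion(y, pred, classes=["bushy", "planar_multipolar", "radiate_multipolar"])
        assert c.loc["planar_multipolar", "radiate_multipolar"] == pytest.approx(0.25, abs=1e-9)
        assert c.loc["radiate_multipolar", "planar_multipolar"] == pytest.approx(0.25, abs=1e-9)
        assert c.loc["bushy", "bushy"] == 1.0


class TestMeasureR2:
    def test_matches_brute_force_sums_of_squares(self):
        t = toy_table(n_per_class=15, n_classes=3, sep=2.0, seed=3)
        r2 = measure_r2(t)
        std, _ = standardize(t)
        for m in ("RMP", "CV"):
            x = std.values[m].to_numpy()
            y = std.labels.to_numpy()
            grand = x.mean()
            ssb = sum((x[y == c].mean() - grand) ** 2 * (y == c).sum() for c in np.unique(y))
            sst = ((x - grand) ** 2).sum()
            assert r2.loc[m, "r2"] == pytest.approx(ssb / sst, abs=1e-12)

    def test_null_effect_near_zero(self):
        t = toy_table(n_per_class=200, n_classes=3, sep=0.0, seed=8)
        r2 = measure_r2(t)
        assert (r2["r2"] < 0.03).all()

    def test_saturated_effect_is_one(self):
        t = toy_table(n_per_class=10, n_classes=3, sep=1.0, seed=0)
        t.values.loc[:, "RMP"] = np.repeat([0.0, 5.0, 10.0], 10)
        r2 = measure_r2(t)
        assert r2.loc["RMP", "r2"] == pytest.approx(1.0, abs=1e-12)

    def test_fdr_adjustment_monotone_in_p(self, cohort_table):
        r2 = measure_r2(cohort_table)
        df = r2.dropna().sort_values("p")
        assert (df["p_fdr"] >= df["p"] - 1e-15).all()


class TestCombinationSearch:
    def test_three_measure_pool_enumerates_seven_subsets(self, cohort_table):
        res = combination_search(cohort_table, sizes=[1, 2, 3], seed=0,
                                 measures=("RMP", "tau_m", "CV"))
        assert len(res.per_subset) == 7  # 2^3 - 1

    def test_counts_and_order_statistics(self, cohort_table):
        res = combination_search(cohort_table, sizes=[1, 2, 12], seed=0)
        counts = res.per_size.set_index("size")["n_subsets"]
        assert counts[1] == 12 and counts[2] == 66 and counts[12] == 1
        assert (res.per_size["best5_mean"] >= res.per_size["mean"] - 1e-12).all()

    def test_bad_size_rejected(self, cohort_table):
        with pytest.raises(ClassificationError, match="sizes"):
            combination_search(cohort_table, sizes=[13])
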