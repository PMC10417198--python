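import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from sepkit.io import ppm_col
from sepkit.models import (
    SingularScatterError,
    SplitSpec,
    cda,
    evaluate_classifier,
    fit_lda,
    nmds,
    pca,
    stratified_split,
    tune_random_forest,
)
from sepkit.preprocess import preprocess, scale, zero_fraction_filter
from sepkit.simulate import generate_profile_table

from conftest import make_profile, null_config, strong_site_config


@pytest.fixture(scope="module")
def separable_scaled():
    table = generate_profile_table(strong_site_config(seed=7))
    scaled, _ = preprocess(table)
    return scaled


@pytest.fixture(scope="module")
def separable_split(separable_scaled):
    return stratified_split(separable_scaled, SplitSpec(seed=7))


class TestStratifiedSplit:
    def test_eight_by_five_gives_32_8(self, profile):
        train, test = stratified_split(profile, SplitSpec(train_fraction=0.8, seed=1))
        assert len(train) == 32
        assert len(test) == 8
        assert test.groupby("site").size().eq(1).all()
        assert set(train["sample_id"]).isdisjoint(test["sample_id"])
        assert len(train) + len(test) == len(profile)

    def test_fraction_one_guard_moves_one_to_test(self, profile):
        train, test = stratified_split(profile, SplitSpec(train_fraction=1.0, seed=0))
        assert test.groupby("site").size().eq(1).all()
        assert len(test) == 8

    def test_deterministic_under_seed(self, profile):
        a = stratified_split(profile, SplitSpec(seed=5))
        b = stratified_split(profile, SplitSpec(seed=5))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        c = stratified_split(profile, SplitSpec(seed=6))
        assert not a[1]["sample_id"].equals(c[1]["sample_id"])

    def test_singleton_group_rejected(self, profile):
        table = pd.concat(
            [profile, profile.iloc[[0]].assign(site="lonely", sample_id="x")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="lonely"):
            stratified_split(table, SplitSpec())

    @pytest.mark.parametrize("sizes", [(2, 3, 7), (5, 5, 5, 5), (2, 2)])
    def test_arbitrary_group_sizes(self, sizes):
        rng = np.random.default_rng(0)
        n = sum(sizes)
        table = make_profile({"P": rng.lognormal(3, 0.3, n)}, groups=1)
        table["site"] = [f"g{i}" for i, s in enumerate(sizes) for _ in range(s)]
        train, test = stratified_split(table, SplitSpec(train_fraction=0.8, seed=2))
        counts = test.groupby("site").size()
        assert (counts >= 1).all()
        for i, s in enumerate(sizes):
            n_train = int(np.floor(0.8 * s + 0.5))
            n_train = min(n_train, s - 1)
            assert (train["site"] == f"g{i}").sum() == max(n_train, 1)


class TestRandomForest:
    def test_singleton_grid_is_best(self, separable_split):
        train, _ = separable_split
        _, report = tune_random_forest(train, mtry_grid=(1,), ntree_grid=(10,), seed=0)
        assert (report.best_mtry, report.best_ntree) == (1, 10)
        assert len(report.tuning) == 1

    def test_separable_data_reaches_100(self, separable_split):
        train, test = separable_split
        model, report = tune_random_forest(
            train, mtry_grid=(3,), ntree_grid=(200,), seed=7
        )
        assert report.cv_accuracy_pct == 100.0
        acc, confusion, mis = evaluate_classifier(model, test)
        assert acc == 100.0
        assert mis == []
        assert (np.diag(confusion.values) == 1).all()

    def test_mtry_beyond_roster_skipped(self, separable_split):
        train, _ = separable_split
        n_el = len([c for c in train.columns if c.endswith("_ppm")])
        with pytest.warns(UserWarning, match="skipping mtry"):
            _, report = tune_random_forest(
                train, mtry_grid=(2, n_el + 5), ntree_grid=(50,), seed=0
            )
        assert report.tuning["mtry"].tolist() == [2]

    def test_empty_grid_rejected(self, separable_split):
        with pytest.raises(ValueError):
            tune_random_forest(separable_split[0], mtry_grid=(), ntree_grid=(100,))

    def test_importances_rank_planted_effects(self, separable_split):
        # elements carrying the planted fingerprints outrank no-effect ones;
        # Gini is used because permutation importance saturates to zero when
        # redundant fingerprints make every feature individually droppable
        train, _ = separable_split
        _, report = tune_random_forest(train, mtry_grid=(3,), ntree_grid=(300,), seed=1)
        imp = report.importances.set_index("element")["mean_decrease_gini"]
        effect = [e for e in ("P", "S", "Cl", "K", "Ca", "Mn", "Ni", "Cu", "Zn", "Sr")
                  if e in imp.index]
        no_effect = [e for e in ("Th", "As") if e in imp.index]
        assert imp.loc[effect].mean() > 2 * imp.loc[no_effect].mean()

    def test_confusion_row_sums_equal_class_counts(self, separable_split):
        train, test = separable_split
        model, _ = tune_random_forest(train, mtry_grid=(3,), ntree_grid=(100,), seed=0)
        _, confusion, _ = evaluate_classifier(model, test)
        counts = test["site"].value_counts()
        for site in counts.index:
            assert confusion.loc[site].sum() == counts[site]


class TestEvaluate:
    class _Stub:
        def __init__(self, preds, roster):
            self.preds = np.asarray(preds)
            self.feature_names_in_ = roster

        def predict(self, X):
            return self.preds

    def _table(self):
        rng = np.random.default_rng(0)
        return make_profile({"P": rng.lognormal(3, 0.2, 8)})

    def test_perfect_predictions(self):
        table = self._table()
        model = self._Stub(table["site"].to_numpy(), ["P"])
        acc, confusion, mis = evaluate_classifier(model, table)
        assert acc == 100.0
        assert mis == []
        assert (confusion.values == np.eye(8)).all()

    def test_seven_of_eight(self):
        table = self._table()
        preds = table["site"].to_numpy().copy()
        preds[-1] = preds[0]
        acc, _, mis = evaluate_classifier(model := self._Stub(preds, ["P"]), table)
        assert acc == pytest.approx(87.5)
        assert len(mis) == 1
        assert mis[0]["predicted"] == preds[0]

    def test_empty_test_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate_classifier(self._Stub([], ["P"]), self._table().iloc[:0])

    def test_roster_mismatch_rejected(self):
        table = self._table()
        with pytest.raises(ValueError, match="roster"):
            evaluate_classifier(self._Stub(table["site"].to_numpy(), ["S"]), table)


class TestLDA:
    def test_separable_training_accuracy_100(self, separable_split):
        _, resub = fit_lda(separable_split[0])
        assert resub == 100.0

    def test_single_sample_class_rejected(self, profile):
        table = pd.concat(
            [profile, profile.iloc[[0]].assign(site="solo", sample_id="x")],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="solo"):
            fit_lda(table)

    def test_collinear_features_rejected(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(3, 0.3, 16)
        table = make_profile({"P": base, "S": 2 * base}, groups=4)
        with pytest.raises(SingularScatterError, match="correlation filter"):
            fit_lda(table)

    def test_permuted_labels_near_chance(self, separable_split):
        train = separable_split[0].copy()
        rng = np.random.default_rng(0)
        accs = []
        for s in range(5):
            train["site"] = np.random.default_rng(s).permutation(
                train["site"].to_numpy()
            )
            _, resub = fit_lda(train)
            accs.append(resub)
        # resubstitution overfits upward of 12.5% chance but stays far from 100
        assert np.mean(accs) < 80.0


class TestPCA:
    def test_variance_explained_sums_to_100(self, separable_scaled):
        res = pca(separable_scaled)
        assert res.variance_explained_pct.sum() == pytest.approx(100.0)

    def test_rank_one_first_component_explains_all(self):
        t = np.linspace(1, 4, 12)
        table = make_profile({"P": 2 * t, "S": 3 * t, "Cl": -t}, groups=4)
        res = pca(table)
        assert res.variance_explained_pct[0] == pytest.approx(100.0)

    def test_loadings_orthogonal(self, separable_scaled):
        L = pca(separable_scaled).loadings.values
        gram = L.T @ L
        assert np.allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-10)

    def test_excess_components_truncated_with_warning(self, separable_scaled):
        with pytest.warns(UserWarning, match="truncat"):
            res = pca(separable_scaled, n_components=100)
        assert res.scores.filter(like="PC").shape[1] <= len(separable_scaled) - 1


class TestNMDS:
    def test_perfect_2d_configuration_near_zero_stress(self):
        rng = np.random.default_rng(2)
        xy = rng.normal(0, 1, (15, 2))
        table = make_profile({"P": xy[:, 0] + 10, "S": xy[:, 1] + 10}, groups=3)
        res = nmds(table, k=2, seed=0)
        assert res.stress < 0.03

    def test_stress_decreases_with_k(self, separable_scaled):
        s2 = nmds(separable_scaled, k=2, seed=3).stress
        s3 = nmds(separable_scaled, k=3, seed=3).stress
        assert s3 <= s2 + 0.02

    def test_degenerate_distances_rejected(self):
        table = make_profile({"P": np.ones(8)})
        with pytest.raises(ValueError, match="degenerate"):
            nmds(table)

    def test_cooked_centroids_cluster_together(self):
        cfg = dataclasses.replace(
            null_config(seed=9),
            cooking_effects={"Cl": 1.6, "Zn": 1.5, "Th": 1.6, "Cu": 1.5,
                             "Mn": 1.5, "Zr": 0.5},
            noise_cv=0.06,
        )
        table = generate_profile_table(cfg)
        reduced, _ = zero_fraction_filter(table)
        scaled, _ = scale(reduced)
        res = nmds(scaled, seed=1)
        cent = res.coordinates.groupby("site")[["NMDS1", "NMDS2"]].mean()
        prep = dict(zip(table["site"], table["preparation"]))
        cooked = [s for s in cent.index if prep[s] == "cooked"]
        raw = [s for s in cent.index if prep[s] == "raw"]
        within = np.mean(
            [np.linalg.norm(cent.loc[a] - cent.loc[b])
             for a in cooked for b in cooked if a < b]
        )
        across = np.mean(
            [np.linalg.norm(cent.loc[a] - cent.loc[b]) for a in cooked for b in raw]
        )
        assert within < across


@pytest.fixture(scope="module")
def cooked_scaled():
    cfg = dataclasses.replace(
        null_config(seed=9),
        cooking_effects={"Cl": 1.6, "Zn": 1.5, "Th": 1.6, "Cu": 1.5,
                         "Mn": 1.5, "Zr": 0.5},
        noise_cv=0.06,
    )
    table = generate_profile_table(cfg)
    reduced, _ = zero_fraction_filter(table)
    scaled, _ = scale(reduced)
    return scaled


class TestCDA:
    def test_axis_count_bound(self, separable_scaled):
        res = cda(separable_scaled)
        assert res.scores.filter(like="CAN").shape[1] <= 7  # 8 groups

    def test_planted_cooking_effect_loads_axis1(self, cooked_scaled):
        res = cda(cooked_scaled)
        ranked = res.structure["CAN1"].abs().sort_values(ascending=False)
        assert set(ranked.index[:6]) == {"Cl", "Zn", "Th", "Cu", "Mn", "Zr"}

    def test_axis1_separates_cooked_from_raw(self, cooked_scaled):
        res = cda(cooked_scaled)
        by_prep = res.scores.groupby("preparation")["CAN1"]
        lo, hi = by_prep.min(), by_prep.max()
        assert hi["cooked"] < lo["raw"] or hi["raw"] < lo["cooked"]

    def test_identical_groups_zero_leading_eigenvalue(self):
        rng = np.random.default_rng(4)
        block = rng.normal(10, 1, (10, 3))
        X = np.vstack([block, block])
        table = make_profile(
            {el: X[:, i] for i, el in enumerate(("P", "S", "Cl"))}, groups=2
        )
        res = cda(table)
        assert res.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)

    def test_two_groups_minimum(self):
        table = make_profile({"P": np.arange(8.0) + 1}, groups=1)
        with pytest.raises(ValueError, match="2 groups"):
            cda(table)

    def test_singular_within_scatter_advises_filter(self):
        rng = np.random.default_rng(1)
        base = rng.lognormal(3, 0.3, 16)
        table = make_profile({"P": base, "S": 2 * base}, groups=4)
        with pytest.raises(SingularScatterError, match="correlation filter"):
            cda(table)
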