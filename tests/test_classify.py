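"""Feature screening, the four classifier families and nested CV."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold

import scglasso as sg


def two_blobs(n_per, d, sep, seed, informative=None):
    """Two Gaussian groups separated by `sep` on `informative` features."""
    rng = np.random.default_rng(seed)
    informative = list(range(d)) if informative is None else informative
    Xa = rng.standard_normal((n_per, d))
    Xb = rng.standard_normal((n_per, d))
    Xb[:, informative] += sep
    X = np.vstack([Xa, Xb])
    y = np.array(["A"] * n_per + ["B"] * n_per)
    labels = tuple(f"f{i}" for i in range(d))
    return sg.FeatureTable(X, labels, y)


class TestVectorize:
    def test_three_region_ordering(self):
        vals = np.array([[2.0, 0.1, 0.2], [0.1, 2.0, 0.3], [0.2, 0.3, 2.0]])
        theta = sg.ConnectivityMatrix(vals, ("r1", "r2", "r3"), "precision")
        vec, labels = sg.vectorize_precision(theta)
        np.testing.assert_allclose(vec, [0.1, 0.2, 0.3])
        assert labels == ("r1--r2", "r1--r3", "r2--r3")

    def test_diagonal_gives_zero_vector(self):
        theta = sg.ConnectivityMatrix(np.diag([1.0, 2.0, 3.0]), role="precision")
        vec, _ = sg.vectorize_precision(theta)
        assert np.all(vec == 0)

    def test_round_trip_against_matrix_rebuild(self, rng):
        Q = rng.standard_normal((5, 5))
        theta = sg.ConnectivityMatrix(Q @ Q.T + 5 * np.eye(5), role="precision")
        vec, _ = sg.vectorize_precision(theta)
        rebuilt = np.zeros((5, 5))
        rebuilt[np.triu_indices(5, 1)] = vec
        rebuilt += rebuilt.T
        np.fill_diagonal(rebuilt, np.diag(theta.values))
        np.testing.assert_allclose(rebuilt, theta.values)


class TestMannWhitney:
    def test_complete_separation_extreme_u(self):
        u, p = sg.mann_whitney_rank([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert u in (0.0, 25.0)
        assert p < 0.01

    def test_identical_multisets_give_central_u(self):
        u, _ = sg.mann_whitney_rank([1.0, 2.0, 3.0], [3.0, 1.0, 2.0])
        assert u == pytest.approx(4.5)  # n1*n2/2

    def test_matches_concordant_pair_count_oracle(self):
        x, y = [1.0, 3.0, 5.0], [2.0, 4.0, 6.0]
        u, _ = sg.mann_whitney_rank(x, y)
        brute = sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0) for xi in x for yj in y
        )
        assert u == pytest.approx(brute)

    def test_all_identical_values_give_p_one(self):
        _, p = sg.mann_whitney_rank([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0


class TestSelectFeatures:
    def test_perfect_separator_found_first(self, rng):
        table = two_blobs(10, 20, sep=8.0, seed=1, informative=[7])
        assert sg.select_features(table, 1)[0] == 7

    def test_full_selection_is_identity_as_set(self, rng):
        table = two_blobs(8, 12, sep=0.5, seed=2)
        idx = sg.select_features(table, 12)
        assert sorted(idx) == list(range(12))

    def test_planted_informative_features_recovered(self):
        informative = [3, 17, 41, 66, 90]
        hits = 0
        for seed in range(20):
            table = two_blobs(40, 100, sep=1.0, seed=seed, informative=informative)
            top5 = set(int(i) for i in sg.select_features(table, 5))
            if len(top5 & set(informative)) >= 4:
                hits += 1
        assert hits >= 18  # >= 4 of 5 recovered in >= 90% of seeds


class TestClassifiers:
    def test_separated_blobs_trained_perfectly_by_all_families(self):
        table = two_blobs(10, 4, sep=10.0, seed=3)
        X, y = table.X, table.y
        lda = sg.ShrunkenLDA(0.5).fit(X, y)
        assert np.mean(lda.predict(X) == y) == 1.0
        assert np.mean(sg.knn_predict(X, y, X, k=3) == y) == 1.0
        assert np.mean(sg.svm_fit(X, y, "poly", 2).predict(X) == y) == 1.0
        assert np.mean(sg.svm_fit(X, y, "rbf", 10.0).predict(X) == y) == 1.0

    def test_gamma_one_equals_diagonal_gaussian_discriminant(self, rng):
        table = two_blobs(15, 3, sep=1.0, seed=4)
        X, y = table.X, table.y
        lda = sg.ShrunkenLDA(1.0).fit(X, y)
        # manual naive (diagonal covariance) discriminant
        var = np.zeros(3)
        mus, priors = [], []
        for c in np.unique(y):
            Xc = X[y == c]
            mus.append(Xc.mean(axis=0))
            priors.append(len(Xc) / len(X))
            var += ((Xc - Xc.mean(axis=0)) ** 2).sum(axis=0)
        var /= len(X) - 2
        scores = np.stack(
            [
                -0.5 * (((X - mu) ** 2) / var).sum(axis=1) + np.log(pr)
                for mu, pr in zip(mus, priors)
            ],
            axis=1,
        )
        manual = np.unique(y)[scores.argmax(axis=1)]
        np.testing.assert_array_equal(lda.predict(X), manual)

    def test_singular_covariance_at_gamma_zero_rejected(self):
        X = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        y = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="gamma"):
            sg.ShrunkenLDA(0.0).fit(X, y)

    def test_knn_hand_enumerated_distances(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [5.0, 5.0]])
        y = np.array(["A", "A", "B", "B"])
        # query (0, 0.2): nearest three are A(0.2), A(0.8), B(1.02) -> A
        assert sg.knn_predict(X, y, [[0.0, 0.2]], k=3)[0] == "A"
        # query near the B corner: B(0.1), A(1.1), A(1.35) -> vote A=2?
        # no: k=1 -> B
        assert sg.knn_predict(X, y, [[1.0, 0.1]], k=1)[0] == "B"


class TestNestedCV:
    def test_duplicated_separable_cohort_is_memorization_free(self):
        table = two_blobs(5, 6, sep=12.0, seed=5)
        X2 = np.vstack([table.X, table.X])
        y2 = np.concatenate([table.y, table.y])
        table2 = sg.FeatureTable(X2, table.feature_labels, y2)
        res = sg.nested_cv(table2, "LDA", grids={"m": [6], "LDA": [0.5]}, seed=0)
        assert res.accuracy == 1.0

    def test_confusion_identities_hold_exactly(self, gld_feature_table):
        res = sg.nested_cv(gld_feature_table, "LDA", seed=7)
        C = res.confusion
        n = C.sum()
        assert res.accuracy * n == C[0, 0] + C[1, 1]
        assert res.sensitivity == pytest.approx(C[1, 1] / C[1].sum())
        assert res.specificity == pytest.approx(C[0, 0] / C[0].sum())
        assert len(res.per_fold) == 10

    def test_no_leakage_from_held_out_rows(self):
        # scrambling the held-out rows (features and labels) of a fold
        # leaves that fold's fitted model untouched
        table = two_blobs(20, 15, sep=1.0, seed=6)
        splits = list(
            StratifiedKFold(5, shuffle=True, random_state=0).split(table.X, table.y)
        )
        grids = {"m": [5, 15], "LDA": [0.5, 1.0]}
        res1 = sg.nested_cv(table, "LDA", grids=grids, seed=1, inner_k=5,
                            outer_splits=splits)

        rng = np.random.default_rng(99)
        for fold_i, (_, te) in enumerate(splits):
            X2 = table.X.copy()
            y2 = table.y.copy()
            X2[te] = rng.standard_normal(X2[te].shape)
            y2[te] = rng.permutation(y2[te])
            table2 = sg.FeatureTable(X2, table.feature_labels, y2)
            res2 = sg.nested_cv(table2, "LDA", grids=grids, seed=1, inner_k=5,
                                outer_splits=splits)
            f1, f2 = res1.per_fold[fold_i], res2.per_fold[fold_i]
            np.testing.assert_array_equal(f1.features, f2.features)
            assert f1.m == f2.m and f1.hyperparam == f2.hyperparam
            assert f1.weights == f2.weights

    def test_permutation_null_is_at_chance(self, gld_feature_table):
        rng = np.random.default_rng(12)
        grids = {"m": [10, 50], "LDA": [0.5]}
        accs = []
        for i in range(10):
            yp = rng.permutation(gld_feature_table.y)
            tp = sg.FeatureTable(gld_feature_table.X,
                                 gld_feature_table.feature_labels, yp)
            accs.append(sg.nested_cv(tp, "LDA", grids=grids, seed=i).accuracy)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.5) <= max(3 * se, 0.12)


class TestFeatureStability:
    def _scripted_result(self):
        # 12 features, 10 folds; feature 2 always selected, feature 5 in
        # 9 folds, feature 7 in 8 folds
        folds = []
        weight_table = {2: [1.0] * 10, 5: [0.5, 0.7, 0.9, 0.4, 0.6, 0.8, 0.3, 1.1, 0.2],
                        7: [2.0] * 8}
        for i in range(10):
            feats, ws = [], {}
            for f, wlist in weight_table.items():
                if i < len(wlist):
                    feats.append(f)
                    ws[f] = wlist[i]
            folds.append(sg.FoldRecord(features=np.array(feats), hyperparam=0.5,
                                       m=len(feats), weights=ws))
        return sg.CVResult(
            confusion=np.array([[5, 0], [0, 5]]), accuracy=1.0, sensitivity=1.0,
            specificity=1.0, per_fold=folds, seed=0, family="LDA",
            classes=("A", "B"), feature_labels=tuple(f"f{i}" for i in range(12)),
        ), weight_table

    def test_counts_flags_and_medians_match_sort_oracle(self):
        res, weight_table = self._scripted_result()
        df = sg.feature_stability(res, top_fraction=0.1)
        assert df.loc[2, "count"] == 10 and df.loc[2, "flagged"]
        assert df.loc[5, "count"] == 9 and df.loc[5, "flagged"]
        assert df.loc[7, "count"] == 8 and not df.loc[7, "flagged"]
        for f, ws in weight_table.items():
            expected = sorted(abs(w) for w in ws)
            k = len(expected)
            med = (expected[k // 2] if k % 2 else
                   0.5 * (expected[k // 2 - 1] + expected[k // 2]))
            assert df.loc[f, "median_weight"] == pytest.approx(med)

    def test_top_fraction_picks_highest_median_among_flagged(self):
        res, _ = self._scripted_result()
        df = sg.feature_stability(res, top_fraction=0.01)  # ceil(0.12) = 1 feature
        assert df["top"].sum() == 1
        # feature 7 has the largest median but is not flagged (8 < 9 folds)
        assert df.loc[2, "top"]  # highest median among flagged (1.0 > 0.6)


class TestCohortPipeline:
    def test_structural_features_not_worse_than_plain_glasso(self):
        # when the group effect lies on structurally supported links,
        # GLd-derived features classify at least as well as GL-derived
        # ones in a clear majority of cohorts
        wins = 0
        n_seeds = 5
        for seed in range(n_seeds):
            cohort = sg.make_cohort(sg.CohortSpec(n_per_group=10, T=800,
                                                  seed=100 + seed))
            acc = {}
            for mode in ("GL", "GLd"):
                table = sg.cohort_feature_table(cohort, mode)
                acc[mode] = sg.nested_cv(table, "LDA", seed=seed).accuracy
            if acc["GLd"] >= acc["GL"]:
                wins += 1
        assert wins >= 0.6 * n_seeds


    def test_feature_table_from_tiny_cohort(self):
        spec = sg.CohortSpec(p=8, n_per_group=3, T=400, effect_links=2, seed=5)
        cohort = sg.make_cohort(spec)
        table = sg.cohort_feature_table(cohort, "GLd")
        assert table.X.shape == (6, 8 * 7 // 2)
        assert set(table.y) == {"A", "B"}
        assert len(table.feature_labels) == 28
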