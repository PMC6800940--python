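"""CART splitting, tree growth, bagging, OOB estimation and serialization."""

import numpy as np
import pytest

from pvcforest import forest as F
from pvcforest.features import LABEL_COLUMN
from pvcforest.synth import FeatureTableConfig, generate_feature_table


def table_xy(df):
    y = df[LABEL_COLUMN].to_numpy().astype(np.int64)
    return df.drop(columns=[LABEL_COLUMN]).to_numpy(dtype=np.float64), y


def brute_force_best_split(X, y, min_leaf):
    """Exhaustive threshold search, written independently of the implementation."""
    n = len(y)
    best = None
    for f in range(X.shape[1]):
        vs = np.unique(X[:, f])
        for thr in (vs[:-1] + vs[1:]) / 2.0:
            left = X[:, f] <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_leaf or nr < min_leaf:
                continue
            def g(labels):
                if labels.size == 0:
                    return 0.0
                p = np.bincount(labels, minlength=2) / labels.size
                return 1.0 - p @ p
            w = (nl / n) * g(y[left]) + (nr / n) * g(y[~left])
            if best is None or w < best[2] - 1e-12:
                best = (f, thr, w)
    return best


class TestGini:
    def test_single_class_is_pure(self):
        assert F.gini([7, 0]) == 0.0

    def test_two_equal_classes_give_half(self):
        assert F.gini([5, 5]) == pytest.approx(0.5)

    def test_three_to_one_counts(self):
        assert F.gini([3, 1]) == pytest.approx(0.375)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            F.gini([0, 0])


class TestGiniIndex:
    def test_pure_partition_is_zero(self):
        y = np.array([0, 0, 1, 1])
        assert F.gini_index(y, [np.array([0, 1]), np.array([2, 3])]) == 0.0

    def test_identity_partition_equals_gini(self):
        y = np.array([0, 1, 1, 0, 1])
        assert F.gini_index(y, [np.arange(5)]) == pytest.approx(F.gini(np.bincount(y)))

    def test_random_binary_split_matches_hand_sum(self, rng):
        y = rng.integers(0, 2, size=30)
        left = np.flatnonzero(rng.random(30) < 0.5)
        right = np.setdiff1d(np.arange(30), left)
        expected = (len(left) / 30) * F.gini(np.bincount(y[left], minlength=2)) \
            + (len(right) / 30) * F.gini(np.bincount(y[right], minlength=2))
        assert F.gini_index(y, [left, right]) == pytest.approx(expected, rel=1e-12)


class TestBestSplit:
    def test_separable_1d_data_splits_at_midgap(self):
        X = np.array([[1.0], [2.0], [8.0], [9.0]])
        y = np.array([0, 0, 1, 1])
        f, thr, gain = F.best_split(X, y, min_samples_leaf=1)
        assert (f, thr) == (0, 5.0)
        assert gain == pytest.approx(0.5)  # parent impurity 0.5, children pure

    def test_uniform_labels_have_no_split(self):
        X = np.arange(10, dtype=float).reshape(-1, 1)
        assert F.best_split(X, np.zeros(10, dtype=int), min_samples_leaf=1) is None

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 50))
        X = rng.normal(size=(n, 2)).round(2)  # rounding forces threshold ties
        y = rng.integers(0, 2, size=n)
        got = F.best_split(X, y, min_samples_leaf=2)
        expected = brute_force_best_split(X, y, min_leaf=2)
        if expected is None:
            assert got is None
        else:
            parent = F.gini(np.bincount(y, minlength=2))
            assert got is not None
            assert parent - got[2] == pytest.approx(expected[2], abs=1e-10)

    def test_agrees_with_sklearn_stump(self, imbalanced_table):
        from sklearn.tree import DecisionTreeClassifier

        X, y = table_xy(imbalanced_table.iloc[:1000])
        stump = DecisionTreeClassifier(max_depth=1, criterion="gini").fit(X, y)
        f, thr, _ = F.best_split(X, y, min_samples_leaf=1)
        assert f == stump.tree_.feature[0]
        assert thr == pytest.approx(stump.tree_.threshold[0], rel=1e-6)


class TestTreeAndForest:
    def test_pure_or_small_sets_become_leaves(self):
        params = F.ForestParams(min_samples_split=10, min_samples_leaf=1)
        X = np.arange(20, dtype=float).reshape(-1, 1)
        pure = F.grow_tree(X, np.zeros(20, dtype=int), params)
        assert pure.is_leaf
        small = F.grow_tree(X[:5], np.array([0, 1, 0, 1, 0]), params)
        assert small.is_leaf

    def test_leaf_counts_conserve_training_points(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:500])
        params = F.ForestParams(min_samples_split=20, min_samples_leaf=5,
                                features_per_split="all", seed=1)
        tree = F.grow_tree(X, y, params)

        def leaf_total(node):
            if node.is_leaf:
                assert node.counts.sum() >= 1
                return int(node.counts.sum())
            return leaf_total(node.left) + leaf_total(node.right)

        assert leaf_total(tree) == len(y)

    def test_single_tree_forest_predicts_like_its_tree(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:800])
        params = F.ForestParams(n_estimators=1, min_samples_split=20,
                                min_samples_leaf=5, seed=4)
        fo = F.fit(X, y, params)
        boot = fo.inbag[0]
        rng = np.random.default_rng(params.seed)
        assert np.array_equal(boot, rng.integers(0, len(y), len(y)))
        assert np.array_equal(F.predict(fo, X), F._apply_tree(fo.trees[0], X))

    def test_fit_is_deterministic_under_fixed_seed(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:600])
        params = F.ForestParams(n_estimators=5, seed=9)
        a, b = F.fit(X, y, params), F.fit(X, y, params)
        assert F.forest_to_json(a) == F.forest_to_json(b)

    def test_bootstrap_unique_fraction_near_632(self):
        m = 5000
        X = np.zeros((m, 1))
        y = np.tile([0, 1], m // 2)
        fo = F.fit(X, y, F.ForestParams(n_estimators=20, seed=2))
        frac = np.mean([np.unique(b).size / m for b in fo.inbag])
        assert frac == pytest.approx(1 - 1 / np.e, abs=0.02)

    def test_single_class_training_is_error(self):
        with pytest.raises(ValueError):
            F.fit(np.zeros((10, 1)), np.zeros(10, dtype=int), F.ForestParams())

    def test_vote_fraction_equals_manual_tally(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:800])
        fo = F.fit(X, y, F.ForestParams(n_estimators=7, min_samples_split=20,
                                        min_samples_leaf=5, seed=0))
        pts = X[:10]
        manual = np.mean([F._apply_tree(t, pts) for t in fo.trees], axis=0)
        assert np.allclose(F.predict_proba(fo, pts), manual)
        assert np.array_equal(F.predict(fo, pts), (manual > 0.5).astype(int))

    def test_vote_tie_falls_to_non_pvc(self):
        leaf0 = F.TreeNode(counts=np.array([5, 0]), prediction=0)
        leaf1 = F.TreeNode(counts=np.array([0, 5]), prediction=1)
        fo = F.Forest(trees=[leaf0, leaf1], inbag=[np.arange(4)] * 2,
                      params=F.ForestParams(n_estimators=2), n_features=1, m=4)
        assert F.predict(fo, np.zeros((3, 1))).tolist() == [0, 0, 0]

    def test_dimension_mismatch_is_error(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:500])
        fo = F.fit(X, y, F.ForestParams(n_estimators=2, seed=0))
        with pytest.raises(ValueError, match="features"):
            F.predict(fo, np.zeros((2, 9)))

    def test_comparable_accuracy_to_sklearn_forest(self, imbalanced_table):
        from sklearn.ensemble import RandomForestClassifier

        X, y = table_xy(imbalanced_table)
        Xtr, ytr, Xte, yte = X[:4000], y[:4000], X[4000:], y[4000:]
        ours = F.fit(Xtr, ytr, F.ForestParams(n_estimators=50, min_samples_split=20,
                                              min_samples_leaf=5, seed=3))
        acc_ours = np.mean(F.predict(ours, Xte) == yte)
        sk = RandomForestClassifier(n_estimators=50, min_samples_split=20,
                                    min_samples_leaf=5, random_state=3).fit(Xtr, ytr)
        acc_sk = sk.score(Xte, yte)
        assert abs(acc_ours - acc_sk) < 0.02

    def test_json_round_trip_preserves_predictions(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:600])
        fo = F.fit(X, y, F.ForestParams(n_estimators=3, seed=5))
        back = F.forest_from_json(F.forest_to_json(fo))
        assert np.array_equal(F.predict(fo, X), F.predict(back, X))
        assert all(np.array_equal(a, b) for a, b in zip(fo.inbag, back.inbag))


class TestOOB:
    def test_oob_votes_match_membership_oracle(self, imbalanced_table):
        X, y = table_xy(imbalanced_table.iloc[:300])
        fo = F.fit(X, y, F.ForestParams(n_estimators=10, min_samples_split=20,
                                        min_samples_leaf=5, seed=6))
        got = F.oob_predictions(fo, X)
        for i in range(len(y)):
            votes = [F._apply_tree(t, X[i:i + 1])[0]
                     for t, boot in zip(fo.trees, fo.inbag) if i not in set(boot.tolist())]
            if not votes:
                assert got[i] == -1
            else:
                assert got[i] == int(sum(votes) > len(votes) - sum(votes))

    def test_separable_data_has_near_zero_oob_error(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (300, 2)), rng.normal(5, 0.1, (300, 2))])
        y = np.repeat([0, 1], 300)
        fo = F.fit(X, y, F.ForestParams(n_estimators=40, min_samples_split=10,
                                        min_samples_leaf=2, seed=0))
        assert F.oob_error(fo, X, y).error <= 0.01


class TestImportance:
    def test_perfectly_separating_feature_ranks_first(self, rng):
        n = 600
        y = rng.integers(0, 2, n)
        X = np.column_stack([rng.normal(size=n), y + rng.normal(0, 0.01, n)])
        recs = F.single_feature_importance(
            X, y, X, y, F.ForestParams(n_estimators=10, min_samples_split=20,
                                       min_samples_leaf=5, seed=0))
        assert recs[0]["feature"] == "f1" and recs[0]["rank"] == 1

    def test_pre_rr_is_most_discriminative_on_synthetic_beats(self):
        train = generate_feature_table(FeatureTableConfig(n=3000, ratio=4.0, seed=31))
        ev = generate_feature_table(FeatureTableConfig(n=3000, ratio=4.0, seed=32))
        Xtr, ytr = table_xy(train)
        Xev, yev = table_xy(ev)
        recs = F.single_feature_importance(
            Xtr, ytr, Xev, yev,
            F.ForestParams(n_estimators=20, min_samples_split=40,
                           min_samples_leaf=10, seed=0),
            feature_names=["pre_RR", "post_RR", "QRS_area", "R_amp"])
        assert recs[0]["feature"] == "pre_RR"

    def test_pure_noise_feature_identifies_few_pvcs(self, rng):
        n = 1200
        y = (rng.random(n) < 0.2).astype(int)
        X = np.column_stack([rng.normal(size=n), y + rng.normal(0, 0.05, n)])
        recs = F.single_feature_importance(
            X, y, X, y, F.ForestParams(n_estimators=10, min_samples_split=40,
                                       min_samples_leaf=10, seed=0))
        by_name = {r["feature"]: r for r in recs}
        assert by_name["f0"]["correct_pvc"] < 0.5 * by_name["f1"]["correct_pvc"]
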