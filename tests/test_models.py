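import itertools

import numpy as np
import pytest
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

from henrec.balancing import LabeledFeatureSet
from henrec.models import (
    DEFAULT_GRIDS,
    ClassifierSpec,
    make_estimator,
    nested_cv,
    standardize,
    tune_hyperparameters,
)
from henrec.synthetic import make_separable_featureset


def featureset(X, y, hens=None):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if hens is None:
        hens = np.array([f"hen{i % 4}" for i in range(len(y))])
    return LabeledFeatureSet(X, y, np.asarray(hens))


class TestClassifierSpec:
    def test_grid_sizes_match_candidate_tables(self):
        sizes = {
            "NB": 1, "kNN": 20, "DT": 24, "RF": 36,
            "LGBM": 192, "SVM": 4, "MLP": 27,
        }
        for family, n in sizes.items():
            assert len(ClassifierSpec(family).candidates()) == n

    def test_tree_families_skip_scaling(self):
        for family in ("DT", "RF", "LGBM"):
            assert not ClassifierSpec(family).needs_scaling
        for family in ("NB", "kNN", "SVM", "MLP"):
            assert ClassifierSpec(family).needs_scaling

    def test_candidate_order_last_parameter_fastest(self):
        cands = ClassifierSpec("kNN").candidates()
        assert cands[0] == {"n_neighbors": 1, "weights": "uniform"}
        assert cands[1] == {"n_neighbors": 1, "weights": "distance"}
        assert cands[2] == {"n_neighbors": 2, "weights": "uniform"}

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec("GBM")

    def test_estimators_instantiate_for_first_candidate(self):
        for family in DEFAULT_GRIDS:
            spec = ClassifierSpec(family)
            est = make_estimator(spec, spec.candidates()[0], seed=0)
            assert hasattr(est, "fit")


class TestStandardize:
    def test_train_becomes_zero_mean_unit_variance(self):
        rng = np.random.default_rng(0)
        tr = featureset(rng.normal(5, 3, (50, 4)), ["A", "B"] * 25)
        te = featureset(rng.normal(5, 3, (10, 4)), ["A", "B"] * 5)
        tr2, te2, params = standardize(tr, te, ClassifierSpec("SVM"))
        assert np.allclose(tr2.X.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(tr2.X.var(axis=0), 1, atol=1e-9)
        assert params is not None

    def test_tree_family_passthrough(self):
        rng = np.random.default_rng(1)
        tr = featureset(rng.normal(size=(20, 3)), ["A", "B"] * 10)
        te = featureset(rng.normal(size=(6, 3)), ["A", "B"] * 3)
        tr2, te2, params = standardize(tr, te, ClassifierSpec("RF"))
        assert params is None
        np.testing.assert_array_equal(tr2.X, tr.X)
        np.testing.assert_array_equal(te2.X, te.X)

    def test_constant_feature_centered_not_scaled(self):
        X = np.column_stack([np.full(20, 7.0), np.arange(20.0)])
        tr = featureset(X, ["A", "B"] * 10)
        tr2, _, _ = standardize(tr, tr, ClassifierSpec("kNN"))
        assert np.allclose(tr2.X[:, 0], 0.0)

    def test_test_transformed_with_train_params(self):
        tr = featureset([[0.0], [2.0]], ["A", "B"])
        te = featureset([[4.0]], ["A"])
        _, te2, params = standardize(tr, te, ClassifierSpec("kNN"))
        # train mean 1, SD 1 -> test value (4-1)/1 = 3
        assert te2.X[0, 0] == pytest.approx(3.0)


def planted_knn_dataset():
    """A set where 1-NN is perfect but larger k misclassifies planted points.

    Class B points sit isolated inside a spread-out A cloud: their nearest
    neighbor is another B point, but 2 of any 3 nearest are A.
    """
    rng = np.random.default_rng(4)
    A = rng.uniform(-10, 10, size=(60, 2))
    pairs = []
    for cx in (-20.0, 20.0):
        for cy in (-20.0, 20.0):
            pairs += [[cx, cy], [cx + 0.1, cy]]
    X = np.vstack([A, np.array(pairs)])
    y = np.array(["A"] * 60 + ["B"] * 8)
    return featureset(X, y)


class TestTuneHyperparameters:
    def test_empty_grid_returns_empty_params(self):
        data = featureset(np.random.default_rng(0).normal(size=(30, 2)), ["A", "B"] * 15)
        assert tune_hyperparameters(data, ClassifierSpec("NB"), seed=0) == {}

    def test_knn_chooses_one_neighbor_on_planted_set(self):
        data = planted_knn_dataset()
        chosen = tune_hyperparameters(data, ClassifierSpec("kNN"), seed=3)
        assert chosen["n_neighbors"] == 1

    def test_choice_matches_brute_force_grid_scoring(self):
        """Independent re-scoring of all 20 kNN grid points agrees."""
        data = planted_knn_dataset()
        seed = 3
        chosen = tune_hyperparameters(data, ClassifierSpec("kNN"), seed=seed)
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=seed % 2**31)
        splits = list(skf.split(np.zeros(len(data)), data.y))
        best, best_score = None, -1.0
        for k, w in itertools.product(range(1, 11), ["uniform", "distance"]):
            scores = []
            for tr_idx, va_idx in splits:
                scaler = StandardScaler().fit(data.X[tr_idx])
                est = KNeighborsClassifier(n_neighbors=k, weights=w)
                est.fit(scaler.transform(data.X[tr_idx]), data.y[tr_idx])
                pred = est.predict(scaler.transform(data.X[va_idx]))
                scores.append(
                    f1_score(data.y[va_idx], pred, average="macro", zero_division=0)
                )
            s = float(np.mean(scores))
            if s > best_score:
                best_score, best = s, {"n_neighbors": k, "weights": w}
        assert chosen == best

    def test_determinism(self):
        data = planted_knn_dataset()
        a = tune_hyperparameters(data, ClassifierSpec("kNN"), seed=11)
        b = tune_hyperparameters(data, ClassifierSpec("kNN"), seed=11)
        assert a == b


class TestNestedCV:
    def test_loho_yields_one_fold_per_hen(self):
        data = make_separable_featureset(n_classes=3, n_per_class=30, n_hens=8, seed=0)
        folds = nested_cv(data, ClassifierSpec("NB"), scheme="loho", seed=0)
        assert len(folds) == 8
        assert sorted(f.test_hen for f in folds) == sorted(set(data.hen_ids))

    def test_loho_partition_ignores_seed(self):
        data = make_separable_featureset(n_classes=3, n_per_class=20, n_hens=4, seed=1)
        a = nested_cv(data, ClassifierSpec("NB"), scheme="loho", seed=1)
        b = nested_cv(data, ClassifierSpec("NB"), scheme="loho", seed=99)
        assert [f.test_hen for f in a] == [f.test_hen for f in b]

    def test_outer_folds_partition_dataset(self):
        data = make_separable_featureset(n_classes=4, n_per_class=25, seed=2)
        for scheme in ("stratified-10-fold", "loho"):
            folds = nested_cv(data, ClassifierSpec("NB"), scheme=scheme, seed=2)
            total = sum(int(f.confusion.sum()) for f in folds)
            assert total == len(data)

    def test_stratified_test_counts_balanced(self):
        data = make_separable_featureset(n_classes=3, n_per_class=100, seed=3)
        folds = nested_cv(data, ClassifierSpec("NB"), scheme="stratified-10-fold", seed=3)
        for f in folds:
            # 100 instances per class over 10 folds -> exactly 10 per fold
            np.testing.assert_array_equal(f.confusion.sum(axis=1), [10, 10, 10])

    def test_ten_fold_membership_depends_on_seed(self):
        data = make_separable_featureset(n_classes=3, n_per_class=40, seed=4)
        a = nested_cv(data, ClassifierSpec("NB"), scheme="stratified-10-fold", seed=1)
        b = nested_cv(data, ClassifierSpec("NB"), scheme="stratified-10-fold", seed=2)
        assert any(
            not np.array_equal(fa.test_indices, fb.test_indices)
            for fa, fb in zip(a, b)
        )

    def test_loho_with_one_hen_rejected(self):
        data = make_separable_featureset(n_classes=2, n_per_class=20, n_hens=1, seed=5)
        with pytest.raises(ValueError, match="2 distinct"):
            nested_cv(data, ClassifierSpec("NB"), scheme="loho", seed=0)

    def test_deterministic_families_reproduce_exactly(self):
        data = make_separable_featureset(n_classes=3, n_per_class=30, seed=6)
        small_knn = ClassifierSpec("kNN", grid={"n_neighbors": [1, 5], "weights": ["uniform"]})
        a = nested_cv(data, small_knn, scheme="stratified-10-fold", seed=7)
        b = nested_cv(data, small_knn, scheme="stratified-10-fold", seed=7)
        for fa, fb in zip(a, b):
            np.testing.assert_array_equal(fa.confusion, fb.confusion)
            assert fa.chosen_params == fb.chosen_params

    @pytest.mark.parametrize("family", ["kNN", "DT", "RF", "LGBM", "SVM", "MLP"])
    def test_separable_two_class_floor(self, family):
        """Every family except NB nails a linearly separable 2-class set."""
        data = make_separable_featureset(
            n_classes=2, n_per_class=30, n_hens=4,
            class_separation=12.0, n_features=4, seed=8,
        )
        if family == "MLP":
            # single candidate with a learning rate that converges on 60 points
            grid = {
                "hidden_layer_sizes": [(100,)],
                "learning_rate_init": [0.01],
                "alpha": [0.0001],
                "early_stopping": [False],
            }
        else:
            grid = {k: v[:1] for k, v in DEFAULT_GRIDS[family].items()}
        spec = ClassifierSpec(family, grid=grid)
        folds = nested_cv(data, spec, scheme="stratified-10-fold", seed=8)
        total = np.sum([f.confusion for f in folds], axis=0)
        assert np.trace(total) == total.sum()  # accuracy 1.0 in every fold

    def test_balancing_runs_inside_training_folds(self):
        counts = [60, 12, 8]
        data = make_separable_featureset(
            n_classes=3, n_per_class=counts, class_separation=8.0, seed=9
        )
        folds = nested_cv(
            data, ClassifierSpec("NB"), scheme="stratified-10-fold",
            seed=9, balancing="smote",
        )
        # test totals are untouched by balancing: they still sum to the data
        assert sum(int(f.confusion.sum()) for f in folds) == sum(counts)
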