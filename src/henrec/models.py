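"""Classifier harness: seven model families, grids, selective scaling, nested CV.

The seven families (NB, kNN, DT, RF, LGBM, SVM, MLP) are delegated to
scikit-learn / LightGBM estimators behind a uniform fit/predict contract.
Hyperparameters are tuned by exhaustive search over the family's candidate
grid, scored by mean macro-F1 over a stratified 5-fold inner CV of each
outer-fold training partition; the outer CV (stratified 10-fold or
leave-one-hen-out) measures generalization. Feature standardization (train
mean/variance) is applied to every family except the tree-based ones, and
training-set balancing — when enabled — runs independently inside every
training partition so synthetic instances never touch validation or test
data.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier

from henrec._seeding import substream_seed
from henrec.balancing import LabeledFeatureSet, apply_balancing
from henrec.signals_io import BEHAVIORS

logger = logging.getLogger(__name__)

FAMILIES = ("NB", "kNN", "DT", "RF", "LGBM", "SVM", "MLP")

#: Tree-based families skip feature standardization.
_TREE_FAMILIES = frozenset({"DT", "RF", "LGBM"})

#: Candidate hyperparameter grids, in listing order (ties in inner-CV score
#: resolve to the earlier candidate). Unlisted hyperparameters stay at the
#: backing implementation's defaults.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "NB": {},
    "kNN": {
        "n_neighbors": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        "weights": ["uniform", "distance"],
    },
    "DT": {
        "max_depth": [5, 7, 10, 12, 15, 20],
        "criterion": ["gini", "entropy"],
        "splitter": ["best", "random"],
    },
    "RF": {
        "n_estimators": [100, 200, 300],
        "criterion": ["gini", "entropy"],
        "max_depth": [5, 10, 50],
        "max_features": ["sqrt", "log2"],
    },
    "LGBM": {
        "min_child_samples": [0, 5, 15, 300],
        "num_leaves": [15, 31, 127],
        "reg_alpha": [0.0, 0.1, 1.0, 10.0],
        "reg_lambda": [0.0, 0.1, 1.0, 10.0],
    },
    "SVM": {
        "C": [0.01, 0.1, 1.0, 10.0],
        "kernel": ["linear"],
    },
    "MLP": {
        "hidden_layer_sizes": [(50,), (75,), (100,)],
        "learning_rate_init": [0.0001, 0.001, 0.01],
        "alpha": [0.00001, 0.0001, 0.001],
        "early_stopping": [True],
    },
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A model family plus its candidate grid and scaling requirement."""

    family: str
    grid: Mapping[str, list] = None  # type: ignore[assignment]
    needs_scaling: bool = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.family])
        if self.needs_scaling is None:
            object.__setattr__(self, "needs_scaling", self.family not in _TREE_FAMILIES)

    def candidates(self) -> list[dict]:
        """Cartesian grid in listing order (last parameter varies fastest)."""
        if not self.grid:
            return [{}]
        keys = list(self.grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.grid[k] for k in keys))
        ]


def make_estimator(spec: ClassifierSpec, params: Mapping, seed: int):
    """Instantiate the backing estimator with chosen params and pinned seed."""
    family = spec.family
    if family == "NB":
        return GaussianNB(**params)
    if family == "kNN":
        return KNeighborsClassifier(**params)
    if family == "DT":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "RF":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "LGBM":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1, **params)
    if family == "SVM":
        return SVC(random_state=seed, **params)
    if family == "MLP":
        return MLPClassifier(random_state=seed, **params)
    raise ValueError(family)


@dataclass
class ScalingParams:
    mean: np.ndarray
    scale: np.ndarray


@dataclass
class FoldResult:
    """Outcome of one outer fold: chosen params and the fold's confusion counts."""

    fold_index: int
    chosen_params: dict
    confusion: np.ndarray
    class_order: tuple[str, ...]
    test_hen: str | None = None
    seed: int = 0
    test_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.confusion.sum() <= 0:
            logger.warning("fold %d has an empty confusion matrix", self.fold_index)


def standardize(
    train: LabeledFeatureSet,
    test: LabeledFeatureSet,
    spec: ClassifierSpec,
) -> tuple[LabeledFeatureSet, LabeledFeatureSet, ScalingParams | None]:
    """Center/scale by training mean and SD unless the family is tree-based.

    Zero-variance features are centered but left unscaled (scale 1). The
    test partition is transformed with the training parameters only.
    """
    if train.feature_names and test.feature_names and train.feature_names != test.feature_names:
        raise ValueError("train/test feature names differ")
    if not spec.needs_scaling:
        return train, test, None
    scaler = StandardScaler().fit(train.X)
    tr = LabeledFeatureSet(
        scaler.transform(train.X), train.y, train.hen_ids,
        train.feature_names, train.provenance,
    )
    te = LabeledFeatureSet(
        scaler.transform(test.X), test.y, test.hen_ids,
        test.feature_names, test.provenance,
    )
    return tr, te, ScalingParams(scaler.mean_.copy(), scaler.scale_.copy())


def _inner_splits(y: np.ndarray, n_inner: int, seed: int):
    """Stratified inner folds, degrading gracefully on tiny classes."""
    _, counts = np.unique(y, return_counts=True)
    n_eff = min(n_inner, int(counts.min()))
    if n_eff < n_inner:
        logger.warning(
            "smallest class has %d instances; inner CV reduced to %d folds",
            counts.min(), n_eff,
        )
    if n_eff < 2:
        return None
    skf = StratifiedKFold(n_splits=n_eff, shuffle=True, random_state=seed % (2**31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return list(skf.split(np.zeros(len(y)), y))


def _fit_predict(
    spec: ClassifierSpec,
    params: Mapping,
    train: LabeledFeatureSet,
    test: LabeledFeatureSet,
    seed: int,
    balancing: str,
    k_smote: int,
    k_enn: int,
) -> np.ndarray:
    """Scale -> balance (train only) -> fit -> predict the test partition.

    Balancing distances are measured in the same space the classifier sees
    (standardized for scaling families, raw for tree families). Returns
    predicted labels for ``test``.
    """
    test_x_before = test.X.copy()
    tr, te, _ = standardize(train, test, spec)
    tr = apply_balancing(tr, balancing, k_smote=k_smote, k_enn=k_enn, seed=seed)
    est = make_estimator(spec, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(tr.X, tr.y)
        pred = est.predict(te.X)
    # leakage audit: the caller's test partition must be bit-identical
    assert np.array_equal(test.X, test_x_before), "test partition mutated"
    assert not np.any(te.provenance == "synthetic"), "synthetic instance in test"
    return pred


def tune_hyperparameters(
    train: LabeledFeatureSet,
    spec: ClassifierSpec,
    seed: int,
    balancing: str = "none",
    k_smote: int = 5,
    k_enn: int = 3,
    n_inner: int = 5,
) -> dict:
    """Exhaustive grid search scored by mean macro-F1 over inner stratified CV.

    Balancing (if enabled) is re-run inside every inner training split so
    no synthetic instance is ever scored. Ties take the earlier candidate
    in grid listing order; an empty grid (NB) returns {} without any CV.
    """
    candidates = spec.candidates()
    if len(candidates) == 1:
        return candidates[0]
    splits = _inner_splits(train.y, n_inner, seed)
    if splits is None:
        logger.warning("too few instances for inner CV; using first grid candidate")
        return candidates[0]
    classes = np.unique(train.y)
    best_params, best_score = candidates[0], -np.inf
    for params in candidates:
        scores = []
        for j, (tr_idx, va_idx) in enumerate(splits):
            inner_seed = substream_seed(seed, "inner", str(j))
            pred = _fit_predict(
                spec, params, train.subset(tr_idx), train.subset(va_idx),
                inner_seed, balancing, k_smote, k_enn,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                scores.append(
                    f1_score(
                        train.y[va_idx], pred, labels=classes,
                        average="macro", zero_division=0,
                    )
                )
        score = float(np.mean(scores))
        if score > best_score:  # strict: ties keep the earlier candidate
            best_score, best_params = score, params
    return best_params


def _outer_splits(
    dataset: LabeledFeatureSet,
    scheme: str,
    n_outer: int,
    seed: int,
):
    """Yield (fold_index, test_hen_or_None, train_idx, test_idx)."""
    if scheme == "loho":
        hens = sorted(set(dataset.hen_ids.tolist()))
        if len(hens) < 2:
            raise ValueError("LOHO requires at least 2 distinct hen_ids")
        for i, hen in enumerate(hens):
            test_mask = dataset.hen_ids == hen
            yield i, hen, np.flatnonzero(~test_mask), np.flatnonzero(test_mask)
    elif scheme == "stratified-10-fold":
        skf = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed % (2**31))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            for i, (tr, te) in enumerate(skf.split(np.zeros(len(dataset)), dataset.y)):
                yield i, None, tr, te
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")


def nested_cv(
    dataset: LabeledFeatureSet,
    spec: ClassifierSpec,
    scheme: str = "stratified-10-fold",
    seed: int = 0,
    balancing: str = "none",
    k_smote: int = 5,
    k_enn: int = 3,
    n_outer: int = 10,
    n_inner: int = 5,
    class_order: Sequence[str] | None = None,
) -> list[FoldResult]:
    """Nested cross-validation: inner tuning inside every outer training fold.

    ``scheme`` is ``stratified-10-fold`` (class-stratified random folds;
    membership depends on the seed) or ``loho`` (one fold per hen, fixed by
    the hen ids; the test hen's instances never reach tuning or training).
    Per fold: tune on outer-train via inner CV -> balance outer-train (if
    enabled) -> selective standardization -> refit -> predict outer-test,
    recorded as a count confusion matrix in fixed class order.
    """
    if class_order is None:
        present = set(np.unique(dataset.y).tolist())
        if present <= set(BEHAVIORS):
            class_order = tuple(b for b in BEHAVIORS if b in present)
        else:
            class_order = tuple(sorted(present))
    else:
        class_order = tuple(class_order)

    results: list[FoldResult] = []
    for i, test_hen, tr_idx, te_idx in _outer_splits(dataset, scheme, n_outer, seed):
        fold_seed = substream_seed(seed, "outer", str(i))
        train, test = dataset.subset(tr_idx), dataset.subset(te_idx)
        missing = set(class_order) - set(np.unique(train.y).tolist())
        if missing:
            logger.warning(
                "fold %d: classes %s absent from training partition", i, sorted(missing)
            )
        params = tune_hyperparameters(
            train, spec, fold_seed, balancing=balancing,
            k_smote=k_smote, k_enn=k_enn, n_inner=n_inner,
        )
        pred = _fit_predict(
            spec, params, train, test, fold_seed, balancing, k_smote, k_enn
        )
        cm = _sk_confusion(test.y, pred, labels=list(class_order))
        results.append(
            FoldResult(
                fold_index=i, chosen_params=params, confusion=cm,
                class_order=class_order, test_hen=test_hen, seed=fold_seed,
                test_indices=np.asarray(te_idx),
            )
        )
    return results
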