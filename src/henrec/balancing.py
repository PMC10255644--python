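"""Training-set class balancing: SMOTE over-sampling and SMOTE+ENN.

SMOTE raises every minority class to the majority count by interpolating
between a real minority instance and one of its k nearest same-class
neighbors. ENN then (optionally) edits the combined set by removing every
instance whose label disagrees with the majority vote of its k nearest
neighbors. Balancing is only ever applied to training partitions; the
provenance flag lets leakage audits verify that no synthetic instance
reaches a validation or test fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from henrec._seeding import substream

logger = logging.getLogger(__name__)

ORIGINAL = "original"
SYNTHETIC = "synthetic"


@dataclass
class LabeledFeatureSet:
    """Parallel arrays of feature vectors, labels, hen ids, and provenance."""

    X: np.ndarray  # (n, p)
    y: np.ndarray  # (n,) class symbols
    hen_ids: np.ndarray  # (n,)
    feature_names: tuple[str, ...] = ()
    provenance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        self.hen_ids = np.asarray(self.hen_ids)
        if self.provenance is None:
            self.provenance = np.full(len(self.y), ORIGINAL, dtype=object)
        else:
            self.provenance = np.asarray(self.provenance)
        n = len(self.X)
        if not (len(self.y) == len(self.hen_ids) == len(self.provenance) == n):
            raise ValueError("parallel arrays must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "LabeledFeatureSet":
        return LabeledFeatureSet(
            self.X[idx], self.y[idx], self.hen_ids[idx],
            self.feature_names, self.provenance[idx],
        )

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    @classmethod
    def from_frame(cls, df) -> "LabeledFeatureSet":
        """Build from a feature table with hen_id/behavior/start_s columns."""
        feature_cols = [
            c for c in df.columns if c not in ("hen_id", "behavior", "start_s")
        ]
        return cls(
            df[feature_cols].to_numpy(dtype=float),
            df["behavior"].to_numpy(),
            df["hen_id"].to_numpy(),
            tuple(feature_cols),
        )


def smote(train: LabeledFeatureSet, k: int = 5, seed: int = 0) -> LabeledFeatureSet:
    """Over-sample every class up to the majority count by interpolation.

    Each synthetic point is x + u (x' - x) for a minority instance x, one
    of its k nearest same-class neighbors x' (Euclidean distance), and
    u ~ Uniform(0, 1). Original instances are never removed or modified.
    Classes with fewer than k+1 instances fall back to k = count - 1
    (logged); a single-instance class is an error.
    """
    counts = train.class_counts()
    if not counts:
        return train
    majority = max(counts.values())
    rng = substream(seed, "smote")
    new_X, new_y = [], []
    for cls in sorted(counts):
        need = majority - counts[cls]
        if need == 0:
            continue
        if counts[cls] < 2:
            raise ValueError(
                f"class {cls!r} has a single instance; SMOTE cannot interpolate"
            )
        k_eff = min(k, counts[cls] - 1)
        if k_eff < k:
            logger.warning(
                "class %s has %d instances; SMOTE neighbor count reduced to %d",
                cls, counts[cls], k_eff,
            )
        Xc = train.X[train.y == cls]
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xc)
        _, nbr = nn.kneighbors(Xc)  # column 0 is self
        base = rng.integers(0, len(Xc), size=need)
        pick = rng.integers(1, k_eff + 1, size=need)
        u = rng.uniform(0.0, 1.0, size=need)
        x0 = Xc[base]
        x1 = Xc[nbr[base, pick]]
        new_X.append(x0 + u[:, None] * (x1 - x0))
        new_y.append(np.full(need, cls, dtype=train.y.dtype))
    if not new_X:
        return train
    Xs = np.vstack([train.X] + new_X)
    ys = np.concatenate([train.y] + new_y)
    hens = np.concatenate(
        [train.hen_ids, np.full(len(ys) - len(train), "synthetic", dtype=object)]
    )
    prov = np.concatenate(
        [train.provenance, np.full(len(ys) - len(train), SYNTHETIC, dtype=object)]
    )
    return LabeledFeatureSet(Xs, ys, hens, train.feature_names, prov)


def enn_filter(data: LabeledFeatureSet, k: int = 3) -> LabeledFeatureSet:
    """Edited nearest neighbors: drop instances out-voted by their neighborhood.

    An instance is kept iff its own label is (one of) the modal label(s)
    among its k nearest neighbors (self excluded). With well-separated
    classes nothing is removed; noisy points inside a foreign cluster go.
    """
    n = len(data)
    if n <= k:
        return data
    nn = NearestNeighbors(n_neighbors=k + 1).fit(data.X)
    _, nbr = nn.kneighbors(data.X)
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        labels = data.y[nbr[i, 1:]]
        vals, counts = np.unique(labels, return_counts=True)
        own = counts[vals == data.y[i]]
        own_count = int(own[0]) if own.size else 0
        if own_count < counts.max():
            keep[i] = False
    return data.subset(keep)


def smoteenn(
    train: LabeledFeatureSet,
    k_smote: int = 5,
    k_enn: int = 3,
    seed: int = 0,
) -> LabeledFeatureSet:
    """SMOTE over-sampling followed by ENN editing of the combined set.

    ENN votes over the post-SMOTE set and may remove instances of any
    class, so the resulting counts are generally unequal.
    """
    oversampled = smote(train, k=k_smote, seed=seed)
    return enn_filter(oversampled, k=k_enn)


def apply_balancing(
    train: LabeledFeatureSet,
    method: str,
    k_smote: int = 5,
    k_enn: int = 3,
    seed: int = 0,
) -> LabeledFeatureSet:
    """Dispatch on config value: ``none`` | ``smote`` | ``smoteenn``."""
    if method == "none":
        return train
    if method == "smote":
        return smote(train, k=k_smote, seed=seed)
    if method == "smoteenn":
        return smoteenn(train, k_smote=k_smote, k_enn=k_enn, seed=seed)
    raise ValueError(f"unknown balancing method {method!r}")
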