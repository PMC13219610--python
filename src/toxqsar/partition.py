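"""Data partitioning: cluster-aware train/test split, k-fold CV plans, and
label permutation for Y-scrambling."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .datamodel import ValidationError


@dataclass
class SplitPlan:
    train_idx: np.ndarray
    test_idx: np.ndarray
    cluster_labels: np.ndarray
    clusters_in_test: set
    rebalanced_count: int
    seed: int

    def __post_init__(self) -> None:
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.test_idx = np.asarray(self.test_idx, dtype=int)
        n = len(self.cluster_labels)
        joint = np.concatenate([self.train_idx, self.test_idx])
        if len(np.intersect1d(self.train_idx, self.test_idx)):
            raise ValidationError("train/test overlap")
        if len(np.union1d(self.train_idx, self.test_idx)) != n or len(joint) != n:
            raise ValidationError("split does not partition all rows")

    def to_json(self) -> str:
        return json.dumps({
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "cluster_labels": np.asarray(self.cluster_labels).tolist(),
            "clusters_in_test": sorted(int(c) for c in self.clusters_in_test),
            "rebalanced_count": self.rebalanced_count,
            "seed": self.seed,
            "index_base": 0,
        })

    @classmethod
    def from_json(cls, s: str) -> "SplitPlan":
        d = json.loads(s)
        return cls(np.array(d["train_idx"]), np.array(d["test_idx"]),
                   np.array(d["cluster_labels"]), set(d["clusters_in_test"]),
                   d["rebalanced_count"], d["seed"])


@dataclass
class FoldPlan:
    """Fold ids in 1..k, one per row."""
    fold_assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_assignments = np.asarray(self.fold_assignments, dtype=int)
        sizes = np.bincount(self.fold_assignments)[1:]
        if sizes.size and sizes.max() - sizes.min() > 1:
            raise ValidationError("fold sizes differ by more than 1")

    @property
    def k(self) -> int:
        return int(self.fold_assignments.max())

    def val_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)

    def to_json(self) -> str:
        return json.dumps({"fold_assignments": self.fold_assignments.tolist(),
                           "seed": self.seed, "index_base": 0})


def cluster_aware_split(X: np.ndarray, frac: float = 0.2,
                        n_clusters: int = 10, n_pcs: Optional[int] = None,
                        seed: int = 0) -> SplitPlan:
    """PCA -> k-means -> whole clusters to test, then exact-count rebalancing.

    Clusters are added to the test side smallest-first until it holds at least
    ``round(frac * n)`` rows; surplus rows closest to the training centroid
    (in PC space) are then transferred back so the test count is exact.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not (0 < frac < 1):
        raise ValidationError("frac must be in (0, 1)")
    if n_clusters > n or n_clusters < 2:
        raise ValidationError("need n >= n_clusters >= 2")
    sd = X.std(axis=0, ddof=0)
    if np.all(sd == 0):
        raise ValidationError("all rows identical; cannot cluster")
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)

    if n_pcs is None:
        full = PCA().fit(Z)
        cum = np.cumsum(full.explained_variance_ratio_)
        n_pcs = min(int(np.searchsorted(cum, 0.95) + 1), 8, Z.shape[1])
    P = PCA(n_components=n_pcs, random_state=seed).fit_transform(Z)

    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(P)

    target = int(round(frac * n))
    sizes = np.bincount(labels, minlength=n_clusters)
    order = np.argsort(sizes, kind="stable")  # smallest-first
    test_clusters, count = [], 0
    for c in order:
        if count >= target:
            break
        test_clusters.append(int(c))
        count += int(sizes[c])

    in_test = np.isin(labels, test_clusters)
    test_idx = np.flatnonzero(in_test)
    train_idx = np.flatnonzero(~in_test)
    moved = 0
    if len(test_idx) > target:
        # move test rows nearest the training centroid back to train
        cen_train = P[train_idx].mean(axis=0)
        d = np.linalg.norm(P[test_idx] - cen_train, axis=1)
        surplus = len(test_idx) - target
        move = test_idx[np.argsort(d, kind="stable")[:surplus]]
        moved = surplus
        keep = ~np.isin(test_idx, move)
        train_idx = np.sort(np.concatenate([train_idx, move]))
        test_idx = test_idx[keep]
    elif len(test_idx) < target:  # pragma: no cover - smallest-first overfills
        cen_test = P[test_idx].mean(axis=0) if len(test_idx) else P.mean(axis=0)
        d = np.linalg.norm(P[train_idx] - cen_test, axis=1)
        deficit = target - len(test_idx)
        move = train_idx[np.argsort(d, kind="stable")[:deficit]]
        moved = deficit
        test_idx = np.sort(np.concatenate([test_idx, move]))
        train_idx = train_idx[~np.isin(train_idx, move)]

    return SplitPlan(np.sort(train_idx), np.sort(test_idx), labels,
                     set(test_clusters), moved, seed)


def kfold(n: int, k: int = 10, seed: int = 0) -> FoldPlan:
    """Seeded balanced fold assignment; the first ``n % k`` folds get the
    extra row."""
    if k > n:
        raise ValidationError("k cannot exceed n")
    if k < 2:
        raise ValidationError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, extra = divmod(n, k)
    assignments = np.empty(n, dtype=int)
    start = 0
    for fold in range(1, k + 1):
        size = base + (1 if fold <= extra else 0)
        assignments[perm[start:start + size]] = fold
        start += size
    return FoldPlan(assignments, seed)


def yscramble_labels(y: np.ndarray, n_perm: int, seed: int = 0) -> list[np.ndarray]:
    """``n_perm`` independent uniform permutations of ``y``."""
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    return [y[rng.permutation(len(y))] for _ in range(n_perm)]
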