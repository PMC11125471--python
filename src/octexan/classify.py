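"""Bagged decision-tree classification of candidate blobs.

Candidates are labeled positive when they overlap the ground truth by
strictly more than 30% of their own area. A bagged ensemble fits each
tree on a bootstrap resample and predicts by majority vote (ties break
toward the negative class, which is precision-conservative); evaluation
uses stratified five-fold cross-validation with shuffling before
partitioning so every fold carries a representative class mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from octexan.blobs import Blob
from octexan.metrics import counts_to_metrics


@dataclass(frozen=True)
class EnsembleConfig:
    n_trees: int = 30
    bootstrap_fraction: float = 1.0
    max_tree_depth: int | None = None
    n_folds: int = 5
    overlap_label_threshold: float = 0.30
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1 or self.n_folds < 2:
            raise ValueError("need n_trees >= 1 and n_folds >= 2")
        if not 0.0 < self.overlap_label_threshold < 1.0:
            raise ValueError("overlap_label_threshold must lie in (0, 1)")
        if not 0.0 < self.bootstrap_fraction <= 1.0:
            raise ValueError("bootstrap_fraction must lie in (0, 1]")


def overlap_fraction(blob: Blob, gt_mask: np.ndarray) -> float:
    """|blob ∩ gt| / |blob|."""
    gt = np.asarray(gt_mask, dtype=bool)
    inter = gt[blob.pixel_set[:, 0], blob.pixel_set[:, 1]].sum()
    return float(inter) / blob.area


def assign_labels(blobs: list[Blob], gt_mask: np.ndarray,
                  threshold: float = 0.30) -> np.ndarray:
    """1 iff a blob overlaps the ground truth by strictly more than ``threshold``."""
    gt = np.asarray(gt_mask, dtype=bool)
    return np.array([1 if overlap_fraction(b, gt) > threshold else 0 for b in blobs], dtype=int)


def stratified_folds(labels: np.ndarray, n_folds: int, rng_seed: int = 0) -> np.ndarray:
    """Shuffled class-stratified fold assignment (one fold id per sample).

    Each class's members are shuffled then dealt round-robin, so per-fold
    class counts differ by at most one sample from perfect balance.
    """
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(rng_seed)
    fold = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < n_folds:
            raise ValueError(f"class {cls} has only {len(idx)} samples for {n_folds} folds")
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


class BaggedTrees:
    """Bootstrap-aggregated decision trees with majority-vote prediction."""

    def __init__(self, cfg: EnsembleConfig):
        cfg.validate()
        self.cfg = cfg
        self.trees: list[DecisionTreeClassifier] = []

    def fit(self, X: np.ndarray, y: np.ndarray, bootstrap: bool = True) -> "BaggedTrees":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.cfg.rng_seed)
        n = len(y)
        m = max(1, int(round(self.cfg.bootstrap_fraction * n)))
        self.trees = []
        for t in range(self.cfg.n_trees):
            idx = rng.integers(0, n, size=m) if bootstrap else np.arange(n)
            seed = int(rng.integers(0, 2**31 - 1))
            tree = DecisionTreeClassifier(
                criterion="gini", max_depth=self.cfg.max_tree_depth, random_state=seed,
            )
            tree.fit(X[idx], y[idx])
            self.trees.append(tree)
        return self

    def vote_scores(self, X: np.ndarray) -> np.ndarray:
        """Mean of tree votes; values lie on the grid k/n_trees."""
        X = np.asarray(X, dtype=float)
        votes = np.stack([t.predict(X) for t in self.trees])
        return votes.mean(axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority vote; exact ties (score 0.5) break toward class 0."""
        return (self.vote_scores(X) > 0.5).astype(int)


def train_bagged_trees(X: np.ndarray, y: np.ndarray, cfg: EnsembleConfig,
                       bootstrap: bool = True) -> BaggedTrees:
    return BaggedTrees(cfg).fit(X, y, bootstrap=bootstrap)


def cross_validate(X: np.ndarray, y: np.ndarray, cfg: EnsembleConfig,
                   model_factory=None) -> dict:
    """Stratified k-fold CV: per-fold predictions + pooled counts/metrics.

    ``model_factory(fold_seed)`` may supply any fit/predict model; the
    default is the bagged-tree ensemble.
    """
    cfg.validate()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, cfg.n_folds, cfg.rng_seed)
    pred = np.full(len(y), -1, dtype=int)
    score = np.full(len(y), np.nan)
    import dataclasses

    for k in range(cfg.n_folds):
        test = folds == k
        train_idx = ~test
        if model_factory is None:
            fold_cfg = dataclasses.replace(cfg, rng_seed=cfg.rng_seed + 1000 * (k + 1))
            model = BaggedTrees(fold_cfg).fit(X[train_idx], y[train_idx])
        else:
            model = model_factory(cfg.rng_seed + 1000 * (k + 1))
            model.fit(X[train_idx], y[train_idx])
        pred[test] = model.predict(X[test])
        if hasattr(model, "vote_scores"):
            score[test] = model.vote_scores(X[test])
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    metrics = counts_to_metrics(tp, fp, fn)
    return {
        "folds": folds, "pred": pred, "score": score,
        "tp": tp, "fp": fp, "fn": fn, "tn": tn, **metrics,
    }


class SingleTree:
    """Plain decision tree with the same interface, for baselining."""

    def __init__(self, rng_seed: int = 0, max_depth: int | None = None):
        self.tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                           random_state=rng_seed)

    def fit(self, X, y):
        self.tree.fit(np.asarray(X, float), np.asarray(y, int))
        return self

    def predict(self, X):
        return self.tree.predict(np.asarray(X, float)).astype(int)


def features_to_matrix(table: pd.DataFrame) -> np.ndarray:
    from octexan.features import FEATURE_NAMES

    return table[FEATURE_NAMES].to_numpy(dtype=float)
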