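"""A C4.5-style decision tree for numeric descriptor tables.

The tree is grown recursively, at each node choosing the binary numeric split
(feature, threshold) maximizing the gain ratio — information gain normalized
by the split's intrinsic information — over candidate thresholds at midpoints
between sorted distinct feature values. Values equal to a threshold are
routed left (the <= convention). Growth stops when a node is pure, has fewer
than ``2 * min_leaf`` rows, or no split achieves positive gain. The grown
tree is then simplified by pessimistic-error pruning: a subtree is replaced
by a leaf when the leaf's estimated error count (the Clopper-Pearson upper
confidence bound on the training error rate at confidence ``pruning_confidence``,
times the node size) does not exceed the sum over its leaves of the same
estimate. Defaults mirror the J48 implementation's documented defaults
(min_leaf=2, pruning_confidence=0.25).

Plain information gain is available behind ``criterion="gain"``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class TreeNode:
    """One node; internal nodes carry a feature+threshold, leaves only counts."""

    class_counts: np.ndarray  # per-class training counts reaching this node
    feature: str | None = None
    feature_idx: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())


@dataclass(frozen=True)
class TreeParams:
    min_leaf: int = 2
    pruning_confidence: float = 0.25
    criterion: str = "gain_ratio"  # or "gain"
    prune: bool = True

    def __post_init__(self) -> None:
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")
        if not 0.0 < self.pruning_confidence < 1.0:
            raise ValueError("pruning_confidence must be in (0, 1)")
        if self.criterion not in ("gain_ratio", "gain"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _best_split_for_feature(
    x: np.ndarray, y: np.ndarray, n_classes: int, min_leaf: int, criterion: str
) -> tuple[float, float, float] | None:
    """Best (score, gain, threshold) for one feature column, or None."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    n = len(xs)
    # candidate boundaries: value changes with both sides >= min_leaf
    change = np.flatnonzero(xs[1:] > xs[:-1]) + 1  # left block size i
    change = change[(change >= min_leaf) & (n - change >= min_leaf)]
    if change.size == 0:
        return None
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), ys] = 1.0
    cum = np.cumsum(onehot, axis=0)
    total = cum[-1]
    parent_h = _entropy(total)
    left = cum[change - 1]
    right = total[None, :] - left
    nl = change.astype(float)
    nr = n - nl

    def block_entropy(counts, sizes):
        with np.errstate(invalid="ignore", divide="ignore"):
            p = counts / sizes[:, None]
            terms = np.where(p > 0, p * np.log2(p), 0.0)
        return -terms.sum(axis=1)

    gain = parent_h - (nl / n) * block_entropy(left, nl) - (nr / n) * block_entropy(right, nr)
    pl, pr = nl / n, nr / n
    split_info = -(pl * np.log2(pl) + pr * np.log2(pr))
    score = gain if criterion == "gain" else gain / split_info
    score = np.where(gain > _EPS, score, -np.inf)
    best = int(np.argmax(score))
    if not np.isfinite(score[best]):
        return None
    i = change[best]
    threshold = (xs[i - 1] + xs[i]) / 2.0
    return float(score[best]), float(gain[best]), threshold


class TreeModel:
    """An induced decision tree plus the configuration that produced it."""

    def __init__(self, root: TreeNode, params: TreeParams, feature_names: list[str], classes: list[str]):
        self.root = root
        self.params = params
        self.feature_names = feature_names
        self.classes_ = classes

    # -- inspection ----------------------------------------------------
    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            return 1 if node.is_leaf else count(node.left) + count(node.right)

        return count(self.root)

    def depth(self) -> int:
        def d(node: TreeNode) -> int:
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def features_used(self) -> set[str]:
        used: set[str] = set()

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                used.add(node.feature)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return used

    # -- prediction ----------------------------------------------------
    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Majority class of the reached leaf for every row; <= routes left."""
        missing = self.features_used() - set(table.columns)
        if missing:
            raise ValueError(f"table is missing model feature(s): {sorted(missing)}")
        cols = {f: table[f].to_numpy(dtype=float) for f in self.features_used()}
        n = len(table)
        labels = np.empty(n, dtype=object)
        for i in range(n):
            node = self.root
            while not node.is_leaf:
                node = node.left if cols[node.feature][i] <= node.threshold else node.right
            labels[i] = self.classes_[int(np.argmax(node.class_counts))]
        return pd.Series(labels, index=table.index, name="predicted")

    # -- serialization -------------------------------------------------
    def to_text(self) -> str:
        lines: list[str] = []

        def walk(node: TreeNode, indent: int) -> None:
            pad = "|   " * indent
            if node.is_leaf:
                cls = self.classes_[int(np.argmax(node.class_counts))]
                counts = "/".join(str(int(c)) for c in node.class_counts)
                lines.append(f"{pad}-> {cls} ({counts})")
                return
            lines.append(f"{pad}{node.feature} <= {node.threshold:.6g}")
            walk(node.left, indent + 1)
            lines.append(f"{pad}{node.feature} > {node.threshold:.6g}")
            walk(node.right, indent + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        def walk(node: TreeNode) -> dict:
            d = {"class_counts": [int(c) for c in node.class_counts]}
            if not node.is_leaf:
                d.update(
                    feature=node.feature,
                    threshold=node.threshold,
                    left=walk(node.left),
                    right=walk(node.right),
                )
            return d

        return {
            "classes": self.classes_,
            "params": {
                "min_leaf": self.params.min_leaf,
                "pruning_confidence": self.params.pruning_confidence,
                "criterion": self.params.criterion,
                "prune": self.params.prune,
            },
            "root": walk(self.root),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, data: dict, feature_names: list[str] | None = None) -> "TreeModel":
        def walk(d: dict) -> TreeNode:
            node = TreeNode(class_counts=np.array(d["class_counts"], dtype=float))
            if "feature" in d:
                node.feature = d["feature"]
                node.threshold = d["threshold"]
                node.left = walk(d["left"])
                node.right = walk(d["right"])
            return node

        return cls(
            root=walk(data["root"]),
            params=TreeParams(**data["params"]),
            feature_names=feature_names or [],
            classes=list(data["classes"]),
        )


def _clopper_pearson_upper(errors: float, n: float, cf: float) -> float:
    """Upper confidence bound on the true error rate given observed errors."""
    if n <= 0:
        return 1.0
    if errors >= n:
        return 1.0
    return float(beta_dist.ppf(1.0 - cf, errors + 1, n - errors))


def _pessimistic_errors(node: TreeNode, cf: float) -> float:
    n = node.n
    errors = n - node.class_counts.max()
    return n * _clopper_pearson_upper(errors, n, cf)


def _prune(node: TreeNode, cf: float) -> float:
    """Bottom-up subtree replacement; returns the subtree's estimated errors."""
    if node.is_leaf:
        return _pessimistic_errors(node, cf)
    subtree = _prune(node.left, cf) + _prune(node.right, cf)
    as_leaf = _pessimistic_errors(node, cf)
    if as_leaf <= subtree + 1e-9:
        node.feature = None
        node.feature_idx = None
        node.threshold = None
        node.left = None
        node.right = None
        return as_leaf
    return subtree


def fit(table: pd.DataFrame, labels: Sequence[str], params: TreeParams | None = None) -> TreeModel:
    """Induce a decision tree on a feature table.

    ``labels`` is aligned with the table rows; classes are the sorted unique
    labels. Single-class input yields a single leaf.
    """
    params = params or TreeParams()
    if table.shape[0] == 0:
        raise ValueError("empty feature table")
    if len(labels) != table.shape[0]:
        raise ValueError("labels length does not match table rows")
    x = table.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-numeric or non-finite feature values")
    classes = sorted(set(labels))
    y = np.array([classes.index(l) for l in labels])
    n_classes = len(classes)
    names = list(table.columns)

    def grow(rows: np.ndarray) -> TreeNode:
        counts = np.bincount(y[rows], minlength=n_classes).astype(float)
        node = TreeNode(class_counts=counts)
        if counts.max() == counts.sum() or len(rows) < 2 * params.min_leaf:
            return node
        best = None  # (score, feature_idx, threshold)
        for j in range(x.shape[1]):
            res = _best_split_for_feature(
                x[rows, j], y[rows], n_classes, params.min_leaf, params.criterion
            )
            if res is None:
                continue
            score, _, threshold = res
            if best is None or score > best[0] + _EPS:
                best = (score, j, threshold)
        if best is None:
            return node
        _, j, threshold = best
        mask = x[rows, j] <= threshold
        node.feature = names[j]
        node.feature_idx = j
        node.threshold = threshold
        node.left = grow(rows[mask])
        node.right = grow(rows[~mask])
        return node

    root = grow(np.arange(len(y)))
    if params.prune:
        _prune(root, params.pruning_confidence)
    return TreeModel(root=root, params=params, feature_names=names, classes=classes)


@dataclass(frozen=True)
class FeatureUsage:
    """Percent-of-iterations presence of each feature across induced trees.

    ``frame`` is indexed by feature, sorted by descending usage (ties
    alphabetical), with columns ``usage`` (percent of all models containing
    the feature), ``block_mean`` and ``block_sd`` (mean and SD of the
    per-block usage percentages over contiguous iteration blocks).
    """

    frame: pd.DataFrame
    n_models: int

    def score(self, feature: str) -> float:
        """Usage percentage of one feature; 0 for features in no model."""
        if feature in self.frame.index:
            return float(self.frame.at[feature, "usage"])
        return 0.0


def feature_usage(models: list[TreeModel], n_blocks: int = 10) -> FeatureUsage:
    """Aggregate feature presence over benchmark iterations."""
    if not models:
        raise ValueError("need at least one model")
    used = [m.features_used() for m in models]
    all_features = sorted(set().union(*used))
    n = len(models)
    n_blocks = min(n_blocks, n)
    presence = np.array([[f in u for u in used] for f in all_features], dtype=float)
    usage = presence.mean(axis=1) * 100.0
    block_edges = np.linspace(0, n, n_blocks + 1).astype(int)
    block_usage = np.stack(
        [presence[:, a:b].mean(axis=1) * 100.0 for a, b in zip(block_edges[:-1], block_edges[1:])],
        axis=1,
    )
    frame = pd.DataFrame(
        {
            "usage": usage,
            "block_mean": block_usage.mean(axis=1),
            "block_sd": block_usage.std(axis=1),
        },
        index=pd.Index(all_features, name="feature"),
    )
    # alphabetical within usage ties (stable sort over a sorted index)
    frame = frame.sort_index().sort_values("usage", ascending=False, kind="stable")
    return FeatureUsage(frame=frame, n_models=n)


def top_k_features(usage: FeatureUsage, k: int = 20) -> list[str]:
    """The k highest-usage feature names; ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    available = list(usage.frame.index)
    if k > len(available):
        logger.warning("requested top %d features but only %d available", k, len(available))
        return available
    return available[:k]
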