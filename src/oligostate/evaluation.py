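"""Performance metrics and the resampled benchmark protocol.

Classification quality is summarized by accuracy, sensitivity, specificity
(all percent) and the Matthews correlation coefficient:

    Ac  = (TP + TN) / (TP + TN + FP + FN) * 100
    Sn  = TP / (TP + FN) * 100
    Sp  = TN / (TN + FP) * 100
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with a degenerate MCC denominator defined as 0 (the random-prediction
convention). The positive class is "monomer" by default.

The benchmark protocol: 100 iterations of a random stratified 80/20
internal/external split; per iteration the tree is fitted on the full
internal set (training surface), assessed by stratified tenfold
cross-validation on the internal set with confusion counts pooled over folds
(CV surface), and applied to the held-out external set (external surface).
Metrics are aggregated as mean +/- SD over iterations. Per-iteration seeds
derive from the master seed through a counter scheme
(``SeedSequence([master, iteration])``), so runs are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .feature_selection import prune_correlated
from .sequence_io import LabelledRecord
from .tree import FeatureUsage, TreeModel, TreeParams, feature_usage, fit

SURFACES = ("train", "cv", "external")
METRIC_NAMES = ("Ac", "Sn", "Sp", "MCC")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn
        )


class Metrics(NamedTuple):
    ac: float
    sn: float
    sp: float
    mcc: float


def confusion(y_true, y_pred, positive: str = "monomer") -> ConfusionCounts:
    """Confusion counts with the given positive class."""
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred, strict=True):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity (percent) and MCC."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero instances")
    ac = (c.tp + c.tn) / c.total * 100.0
    sn = c.tp / (c.tp + c.fn) * 100.0 if (c.tp + c.fn) else 0.0
    sp = c.tn / (c.tn + c.fp) * 100.0 if (c.tn + c.fp) else 0.0
    denom = math.sqrt(
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / denom if denom else 0.0
    return Metrics(ac, sn, sp, mcc)


def _iteration_seed(master: int, iteration: int) -> int:
    """Deterministic per-iteration seed below 2^31."""
    return int(np.random.SeedSequence([master, iteration]).generate_state(1)[0] % (2**31))


def split_80_20(
    labelled: list[LabelledRecord], seed: int, external_fraction: float = 0.2
) -> tuple[list[LabelledRecord], list[LabelledRecord]]:
    """Random stratified internal/external partition (largest-remainder sizes).

    Class proportions are preserved within rounding; the partition is
    disjoint, covers the input, and is reproducible from the seed.
    """
    per_class_counts: dict[str, int] = {}
    for lr in labelled:
        per_class_counts[lr.label] = per_class_counts.get(lr.label, 0) + 1
    for cls, n in per_class_counts.items():
        if n < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
    id_label = [(lr.record.id, lr.label) for lr in labelled]
    internal_ids, external_ids = _stratified_split_ids(id_label, seed, external_fraction)
    by_id = {lr.record.id: lr for lr in labelled}
    return [by_id[i] for i in internal_ids], [by_id[i] for i in external_ids]


def _fit_on(table: pd.DataFrame, ids: list[str], labels: dict[str, str], params: TreeParams) -> TreeModel:
    sub = table.loc[ids]
    return fit(sub, [labels[i] for i in ids], params)


def tenfold_cv(
    table: pd.DataFrame,
    labels: dict[str, str],
    seed: int,
    params: TreeParams | None = None,
    positive: str = "monomer",
    n_folds: int = 10,
) -> ConfusionCounts:
    """Stratified k-fold CV on the internal set, confusion pooled over folds."""
    params = params or TreeParams()
    ids = list(table.index)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} records for {n_folds}-fold CV")
    y = [labels[i] for i in ids]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in skf.split(np.zeros(len(ids)), y):
        train_ids = [ids[i] for i in train_idx]
        test_ids = [ids[i] for i in test_idx]
        model = _fit_on(table, train_ids, labels, params)
        preds = model.predict(table.loc[test_ids])
        pooled = pooled + confusion([labels[i] for i in test_ids], preds, positive)
    return pooled


@dataclass(frozen=True)
class PerformanceReport:
    """Per-surface iteration metrics and their mean +/- SD aggregation."""

    per_iteration: dict[str, pd.DataFrame]  # surface -> (n_iterations x 4) frame
    n_iterations: int

    def mean(self, surface: str) -> Metrics:
        m = self.per_iteration[surface].mean()
        return Metrics(*(m[k] for k in METRIC_NAMES))

    def sd(self, surface: str) -> Metrics:
        if self.n_iterations == 1:
            return Metrics(0.0, 0.0, 0.0, 0.0)
        s = self.per_iteration[surface].std(ddof=1)
        return Metrics(*(s[k] for k in METRIC_NAMES))

    def summary(self) -> pd.DataFrame:
        """Mean +/- SD table: rows = surface, columns = Ac/Sn/Sp/MCC."""
        rows = {}
        for surface in SURFACES:
            mean, sd = self.mean(surface), self.sd(surface)
            rows[surface] = {
                name: f"{m:.2f} ± {s:.2f}"
                for name, m, s in zip(METRIC_NAMES, mean, sd)
            }
        return pd.DataFrame(rows).T[list(METRIC_NAMES)]

    def to_csv(self, path) -> None:
        """Flat layout: one row per surface with mean and SD columns."""
        out = {}
        for surface in SURFACES:
            mean, sd = self.mean(surface), self.sd(surface)
            row = {}
            for name, m, s in zip(METRIC_NAMES, mean, sd):
                row[f"{name}_mean"] = round(m, 6)
                row[f"{name}_sd"] = round(s, 6)
            out[surface] = row
        pd.DataFrame(out).T.rename_axis("surface").to_csv(path)


@dataclass(frozen=True)
class BenchmarkOutcome:
    report: PerformanceReport
    usage: FeatureUsage
    models: list[TreeModel] = field(repr=False, default_factory=list)


def benchmark(
    table: pd.DataFrame,
    labels: dict[str, str],
    n_iterations: int = 100,
    seed: int = 0,
    params: TreeParams | None = None,
    positive: str = "monomer",
    prune_cutoff: float | None = 0.7,
    prune_on: str = "internal",
) -> BenchmarkOutcome:
    """The full resampling protocol on a precomputed feature table.

    Per iteration: stratified 80/20 split; correlation pruning fitted on the
    internal rows only (``prune_on="internal"``, the leakage-safe default) or
    on the whole table once (``prune_on="all"``); tree fitted on the pruned
    internal set (train surface), tenfold CV on the internal set (cv
    surface), prediction of the untouched external set (external surface).
    ``prune_cutoff=None`` disables pruning.
    """
    params = params or TreeParams()
    if prune_on not in ("internal", "all"):
        raise ValueError("prune_on must be 'internal' or 'all'")
    ids = list(table.index)
    id_label = [(i, labels[i]) for i in ids]

    whole_kept = None
    if prune_cutoff is not None and prune_on == "all":
        whole_kept = list(prune_correlated(table, prune_cutoff).kept)

    per_surface = {s: [] for s in SURFACES}
    models: list[TreeModel] = []
    for it in range(n_iterations):
        it_seed = _iteration_seed(seed, it)
        internal_ids, external_ids = _stratified_split_ids(id_label, it_seed)
        if prune_cutoff is not None and prune_on == "internal":
            kept = list(prune_correlated(table.loc[internal_ids], prune_cutoff).kept)
        else:
            kept = whole_kept if whole_kept is not None else list(table.columns)
        sub = table[kept]
        model = _fit_on(sub, internal_ids, labels, params)
        models.append(model)

        train_pred = model.predict(sub.loc[internal_ids])
        c_train = confusion([labels[i] for i in internal_ids], train_pred, positive)
        c_cv = tenfold_cv(sub.loc[internal_ids], labels, it_seed, params, positive)
        ext_pred = model.predict(sub.loc[external_ids])
        c_ext = confusion([labels[i] for i in external_ids], ext_pred, positive)

        for surface, c in zip(SURFACES, (c_train, c_cv, c_ext)):
            per_surface[surface].append(metrics(c))

    per_iteration = {
        s: pd.DataFrame(per_surface[s], columns=list(METRIC_NAMES)) for s in SURFACES
    }
    report = PerformanceReport(per_iteration=per_iteration, n_iterations=n_iterations)
    return BenchmarkOutcome(report=report, usage=feature_usage(models), models=models)


def _stratified_split_ids(
    id_label: list[tuple[str, str]], seed: int, external_fraction: float = 0.2
) -> tuple[list[str], list[str]]:
    """80/20 id partition; same stratified largest-remainder scheme as
    :func:`split_80_20` but operating on (id, label) pairs."""
    if len(id_label) < 5:
        raise ValueError("need at least 5 records to split 80/20")
    by_class: dict[str, list[str]] = {}
    for rid, label in id_label:
        by_class.setdefault(label, []).append(rid)
    if len(by_class) < 2:
        raise ValueError("both classes must be present")
    total_external = round(external_fraction * len(id_label))
    quotas = {c: external_fraction * len(m) for c, m in by_class.items()}
    counts = {c: math.floor(q) for c, q in quotas.items()}
    leftover = total_external - sum(counts.values())
    for c in sorted(quotas, key=lambda c: (counts[c] - quotas[c], c))[: max(leftover, 0)]:
        counts[c] += 1
    rng = np.random.default_rng(seed)
    internal: list[str] = []
    external: list[str] = []
    for cls in sorted(by_class):
        members = by_class[cls]
        perm = rng.permutation(len(members))
        chosen = set(perm[: counts[cls]])
        for i, rid in enumerate(members):
            (external if i in chosen else internal).append(rid)
    return internal, external
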