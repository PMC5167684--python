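"""Model/Results interface over the oligomeric-state pipeline.

:class:`OligomerStateModel` is constructed from data (a precomputed feature
table, or sequences via :meth:`~OligomerStateModel.from_sequences` /
:meth:`~OligomerStateModel.from_files`); :meth:`~OligomerStateModel.fit`
returns an :class:`OligomerStateResults` carrying the induced tree, the kept
feature set, training diagnostics and a ``summary()`` table;
:meth:`~OligomerStateModel.benchmark` runs the resampled evaluation protocol
and returns a :class:`BenchmarkResults` with per-surface mean +/- SD metrics
and feature-usage scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import evaluation
from .descriptors import DescriptorConfig, compute_class, compute_selected
from .feature_selection import PruneResult, prune_correlated
from .sequence_io import LabelledRecord, ProteinRecord, parse_fasta, read_labels
from .tree import FeatureUsage, TreeModel, TreeParams, top_k_features
from .tree import fit as fit_tree


class OligomerStateModel:
    """A monomer/oligomer classifier specification bound to data.

    Parameters
    ----------
    features:
        Feature table (rows = sequence ids, columns = descriptors).
    labels:
        id -> {monomer, oligomer} mapping covering every row.
    tree_params:
        C4.5 hyperparameters (defaults: min_leaf=2, pruning confidence 0.25).
    prune_cutoff:
        Pearson |r| cutoff for collinearity pruning before tree induction;
        ``None`` disables pruning.
    positive:
        Positive class for Sn/Sp/MCC.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels: dict[str, str],
        tree_params: TreeParams | None = None,
        prune_cutoff: float | None = 0.7,
        positive: str = "monomer",
    ):
        missing = [i for i in features.index if i not in labels]
        if missing:
            raise ValueError(f"labels missing for ids: {missing[:5]}")
        self.features = features
        self.labels = {i: labels[i] for i in features.index}
        self.tree_params = tree_params or TreeParams()
        self.prune_cutoff = prune_cutoff
        self.positive = positive

    # -- constructors --------------------------------------------------
    @classmethod
    def from_sequences(
        cls,
        records: list[ProteinRecord] | list[LabelledRecord],
        labels: dict[str, str] | None = None,
        descriptor_class: str = "aac_dpc_tpc",
        config: DescriptorConfig | None = None,
        selected_features: list[str] | None = None,
        **kwargs,
    ) -> "OligomerStateModel":
        """Build from records, computing descriptors of one class (or only
        ``selected_features`` in production mode)."""
        if records and isinstance(records[0], LabelledRecord):
            labels = {lr.record.id: lr.label for lr in records}
            records = [lr.record for lr in records]
        if labels is None:
            raise ValueError("labels are required when passing bare records")
        config = config or DescriptorConfig()
        if selected_features:
            table = compute_selected(records, selected_features, config)
        else:
            table = compute_class(records, descriptor_class, config)
        return cls(table, labels, **kwargs)

    @classmethod
    def from_files(
        cls,
        fasta_path,
        labels_path,
        descriptor_class: str = "aac_dpc_tpc",
        **kwargs,
    ) -> "OligomerStateModel":
        with open(fasta_path) as fh:
            records = parse_fasta(fh)
        with open(labels_path) as fh:
            labelled = read_labels(fh, records)
        return cls.from_sequences(labelled, descriptor_class=descriptor_class, **kwargs)

    # -- estimation ----------------------------------------------------
    def fit(self) -> "OligomerStateResults":
        """Prune collinear features, induce the tree, score the training set."""
        if self.prune_cutoff is not None:
            prune = prune_correlated(self.features, self.prune_cutoff)
            kept = self.features[list(prune.kept)]
        else:
            prune = None
            kept = self.features
        y = [self.labels[i] for i in kept.index]
        tree = fit_tree(kept, y, self.tree_params)
        preds = tree.predict(kept)
        counts = evaluation.confusion(y, preds, self.positive)
        return OligomerStateResults(
            model=self, tree=tree, prune=prune, training_confusion=counts
        )

    def benchmark(
        self,
        n_iterations: int = 100,
        seed: int = 0,
        prune_on: str = "internal",
    ) -> "BenchmarkResults":
        """Run the 80/20 x tenfold-CV protocol for ``n_iterations``."""
        outcome = evaluation.benchmark(
            self.features,
            self.labels,
            n_iterations=n_iterations,
            seed=seed,
            params=self.tree_params,
            positive=self.positive,
            prune_cutoff=self.prune_cutoff,
            prune_on=prune_on,
        )
        return BenchmarkResults(model=self, outcome=outcome)


@dataclass
class OligomerStateResults:
    """A fitted tree with its pruning record and training diagnostics."""

    model: OligomerStateModel
    tree: TreeModel
    prune: PruneResult | None
    training_confusion: evaluation.ConfusionCounts

    @property
    def training_metrics(self) -> evaluation.Metrics:
        return evaluation.metrics(self.training_confusion)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        """Predicted class per row of a new feature table."""
        return self.tree.predict(features)

    def predict_records(self, records: list[ProteinRecord]) -> pd.Series:
        """Predict directly from records, computing only the tree's features."""
        needed = sorted(self.tree.features_used())
        if not needed:  # single-leaf tree: constant prediction
            cls = self.tree.classes_[int(self.tree.root.class_counts.argmax())]
            return pd.Series([cls] * len(records), index=[r.id for r in records])
        table = compute_selected(records, needed)
        return self.tree.predict(table)

    def summary(self) -> str:
        m = self.training_metrics
        lines = [
            "Oligomeric state decision tree",
            "==============================",
            f"observations:      {self.training_confusion.total}",
            f"features offered:  {self.model.features.shape[1]}"
            + (
                f"  (kept after |r|>{self.model.prune_cutoff} pruning: {len(self.prune.kept)})"
                if self.prune is not None
                else ""
            ),
            f"features used:     {len(self.tree.features_used())}",
            f"leaves / depth:    {self.tree.n_leaves()} / {self.tree.depth()}",
            f"training Ac/Sn/Sp: {m.ac:.2f}% / {m.sn:.2f}% / {m.sp:.2f}%",
            f"training MCC:      {m.mcc:.4f}",
            "",
            "Decision rules:",
            self.tree.to_text(),
        ]
        return "\n".join(lines)


@dataclass
class BenchmarkResults:
    """Aggregated benchmark metrics and feature usage."""

    model: OligomerStateModel
    outcome: evaluation.BenchmarkOutcome

    @property
    def report(self) -> evaluation.PerformanceReport:
        return self.outcome.report

    @property
    def usage(self) -> FeatureUsage:
        return self.outcome.usage

    def top_features(self, k: int = 20) -> list[str]:
        return top_k_features(self.usage, k)

    def summary(self) -> str:
        table = self.report.summary()
        top = self.usage.frame.head(10)
        lines = [
            f"Benchmark over {self.report.n_iterations} iterations "
            f"(80/20 split, tenfold CV; mean ± SD)",
            table.to_string(),
            "",
            "Top feature usage (% of iterations):",
            top.to_string(float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines)
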