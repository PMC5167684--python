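"""Collinearity pruning by pairwise Pearson correlation.

Highly intercorrelated descriptors add model complexity without information;
they are removed with the classic findCorrelation-style iterative rule: while
any pair of kept features has |r| above the cutoff (default 0.7), take the
worst offending pair and drop the member with the larger mean absolute
correlation against the remaining features. After pruning, no kept pair
exceeds the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PruneResult:
    kept: tuple[str, ...]
    removed: tuple[str, ...]
    cutoff: float
    #: zero-variance features (correlations defined as 0; uninformative but
    #: not removed by the pairwise rule)
    uninformative: tuple[str, ...] = ()

    def to_frame(self, table: pd.DataFrame | None = None) -> pd.DataFrame:
        """Kept/removed listing, with mean |r| when the source table is given."""
        rows = [(f, "kept") for f in self.kept] + [(f, "removed") for f in self.removed]
        out = pd.DataFrame(rows, columns=["feature", "status"]).set_index("feature")
        if table is not None:
            corr = correlation_matrix(table)
            absr = corr.abs().to_numpy()
            np.fill_diagonal(absr, np.nan)
            out["mean_abs_r"] = pd.Series(np.nanmean(absr, axis=1), index=corr.index)
        return out


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Pearson correlation matrix with unit diagonal.

    Zero-variance columns get correlation 0 against everything (their own
    diagonal stays 1); at least 3 rows are required for a meaningful r.
    """
    if table.shape[0] < 3:
        raise ValueError("correlation matrix needs at least 3 rows")
    x = table.to_numpy(dtype=float)
    sd = x.std(axis=0)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=table.columns, columns=table.columns)


def prune_correlated(table: pd.DataFrame, cutoff: float = 0.7) -> PruneResult:
    """Iteratively remove one member of each |r| > cutoff pair.

    Deterministic: the worst pair is located in column order, and ties in the
    mean-|r| comparison drop the later column.
    """
    if not 0.0 < cutoff <= 1.0:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    corr = correlation_matrix(table)
    names = list(table.columns)
    a = np.abs(corr.to_numpy())
    np.fill_diagonal(a, 0.0)
    sd = table.to_numpy(dtype=float).std(axis=0)
    uninformative = tuple(n for n, s in zip(names, sd) if s == 0)

    k = len(names)
    active = np.ones(k, dtype=bool)
    rowsum = a.sum(axis=1)  # sum |r| against all other (currently active) features
    removed: list[str] = []
    # Correlations never change during removal, so the running maximum over
    # active pairs is simply the next entry of the pairs-sorted-once list
    # whose endpoints are both still active. Ties follow row-major order,
    # matching a repeated-argmax formulation exactly.
    iu, ju = np.triu_indices(k, k=1)
    offending = a[iu, ju] > cutoff
    iu, ju, vals = iu[offending], ju[offending], a[iu, ju][offending]
    order = np.lexsort((ju, iu, -vals))
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if not (active[i] and active[j]):
            continue
        n_active = active.sum()
        mean_i = rowsum[i] / (n_active - 1)
        mean_j = rowsum[j] / (n_active - 1)
        drop = i if mean_i > mean_j else j if mean_j > mean_i else max(i, j)
        removed.append(names[drop])
        active[drop] = False
        rowsum -= a[:, drop]
        rowsum[drop] = 0.0
    kept = tuple(n for n, keep in zip(names, active) if keep)
    return PruneResult(
        kept=kept, removed=tuple(removed), cutoff=cutoff, uninformative=uninformative
    )
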