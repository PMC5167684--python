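"""Greedy identity-threshold sequence clustering (CD-HIT-style).

Redundant sequences — e.g. site-directed mutants of a handful of wild types —
inflate apparent classifier performance, so the data set is reduced before
model building: sequences are sorted longest-first and each joins the first
existing cluster whose representative it matches at or above the identity
threshold, otherwise it founds a new cluster. Retained sequences are the
cluster representatives.

Identity follows the CD-HIT convention: identical positions of a global
pairwise alignment divided by the length of the shorter sequence. The
alignment is a full dynamic-programming global alignment (match +1,
mismatch 0, simple gap penalty) rather than a k-mer-screened heuristic; at
the few hundred sequences typical here the exact O(n^2) computation is
affordable and auditable. An exact composition bound (shared residue counts
over the shorter length) skips alignments that provably cannot reach the
threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .sequence_io import ALPHABET, ProteinRecord

_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}


def _composition_vector(rec: ProteinRecord) -> np.ndarray:
    codes = np.fromiter((_AA_INDEX[ch] for ch in rec.sequence), dtype=np.int64)
    return np.bincount(codes, minlength=20)


@dataclass(frozen=True)
class ClusterResult:
    """Outcome of greedy clustering at one identity threshold."""

    threshold: float
    clusters: list[tuple[str, list[str]]]  # (representative id, member ids incl. rep)
    retained: list[ProteinRecord]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    def membership_rows(self) -> list[tuple[str, str]]:
        """(member_id, representative_id) pairs for CSV export."""
        return [(m, rep) for rep, members in self.clusters for m in members]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


def _identity_upper_bound(a: ProteinRecord, b: ProteinRecord) -> float:
    # Aligned identical positions can never exceed the shared composition.
    ca, cb = Counter(a.sequence), Counter(b.sequence)
    shared = sum(min(ca[ch], cb[ch]) for ch in ca)
    return shared / min(len(a), len(b))


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global-alignment identity over the shorter sequence length, in [0, 1]."""
    if a.sequence == b.sequence:
        return 1.0
    alignment = _ALIGNER.align(a.sequence, b.sequence)[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


def greedy_cluster(records: list[ProteinRecord], threshold: float) -> ClusterResult:
    """Cluster records at an identity threshold; retain representatives.

    Records are processed longest-first (ties keep input order, so results
    are reproducible); each joins the first cluster whose representative
    identity is >= threshold.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    ordered = sorted(records, key=lambda r: -len(r))  # stable: input order on ties
    # residue-count vectors, cached once: the composition bound is then O(20)
    comp = {rec.id: _composition_vector(rec) for rec in ordered}
    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    for rec in ordered:
        placed = False
        for i, rep in enumerate(reps):
            shorter = min(len(rec), len(rep))
            bound = np.minimum(comp[rec.id], comp[rep.id]).sum() / shorter
            if bound < threshold:
                continue
            if pairwise_identity(rec, rep) >= threshold:
                members[i].append(rec.id)
                placed = True
                break
        if not placed:
            reps.append(rec)
            members.append([rec.id])
    clusters = [(rep.id, mem) for rep, mem in zip(reps, members)]
    return ClusterResult(threshold=threshold, clusters=clusters, retained=list(reps))
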