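"""Conjoint triad descriptors.

Residues are grouped into seven classes by side-chain dipole and volume and
every overlapping window of three consecutive residues is counted as a class
triad, giving 7^3 = 343 counts which are max-normalized within the sequence
(the largest count maps to 1).
"""

from __future__ import annotations

import itertools

import numpy as np

from ..scales import load_ctriad_classes
from ..sequence_io import ProteinRecord

CTRIAD_NAMES = tuple(
    f"CTriad.{a}{b}{c}" for a, b, c in itertools.product(range(1, 8), repeat=3)
)


def compute_ctriad(record: ProteinRecord) -> np.ndarray:
    if len(record) < 3:
        raise ValueError(f"record {record.id!r}: conjoint triads need at least 3 residues")
    mapping = load_ctriad_classes()
    cls = np.fromiter(
        (mapping[ch] - 1 for ch in record.sequence), dtype=np.int64, count=len(record)
    )
    codes = (cls[:-2] * 7 + cls[1:-1]) * 7 + cls[2:]
    counts = np.bincount(codes, minlength=343).astype(float)
    return counts / counts.max()
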