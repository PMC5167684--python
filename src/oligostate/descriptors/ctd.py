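"""Composition/Transition/Distribution (CTD) descriptors.

Residues are mapped into three groups per physicochemical property (seven
Dubchak-style properties: hydrophobicity, normalized van der Waals volume,
polarity, polarizability, charge, secondary structure, solvent
accessibility). Per property:

* composition  C_r = n_r / N for r = 1..3;
* transition   T_rs = (n_rs + n_sr) / (N - 1) for rs in {12, 13, 23};
* distribution: for each group, the sequence positions at which the first,
  25%, 50%, 75% and 100% of that group's residues have occurred, as percent
  of N. The q-quantile occurrence is the ceil(q * n_r)-th one; an absent
  group contributes five zeros.

Total width 7 x (3 + 3 + 15) = 147.
"""

from __future__ import annotations

import math

import numpy as np

from ..scales import CTD_PROPERTIES, load_ctd_groups
from ..sequence_io import ProteinRecord

_QUANT = (0.0, 0.25, 0.50, 0.75, 1.0)  # 0.0 stands for "first occurrence"
_QLABEL = ("first", "p25", "p50", "p75", "p100")

CTD_NAMES = tuple(
    name
    for prop in CTD_PROPERTIES
    for name in (
        [f"CTD.{prop}.comp.g{r}" for r in (1, 2, 3)]
        + [f"CTD.{prop}.trans.g{rs}" for rs in ("12", "13", "23")]
        + [f"CTD.{prop}.dist.g{r}.{q}" for r in (1, 2, 3) for q in _QLABEL]
    )
)


def encode_groups(sequence: str, groups: tuple[str, str, str]) -> np.ndarray:
    """Map residues onto group indices 1..3 for one property."""
    lookup = {}
    for gi, members in enumerate(groups, start=1):
        for ch in members:
            lookup[ch] = gi
    return np.fromiter((lookup[ch] for ch in sequence), dtype=np.int64, count=len(sequence))


def _property_block(enc: np.ndarray) -> list[float]:
    n = len(enc)
    out: list[float] = []
    counts = np.bincount(enc, minlength=4)[1:4]
    out.extend(counts / n)  # composition
    trans = {"12": 0, "13": 0, "23": 0}
    for a, b in zip(enc[:-1], enc[1:]):
        if a != b:
            key = f"{min(a, b)}{max(a, b)}"
            trans[key] += 1
    out.extend(trans[k] / (n - 1) for k in ("12", "13", "23"))  # transition
    for g in (1, 2, 3):  # distribution
        positions = np.flatnonzero(enc == g) + 1  # 1-based
        n_r = len(positions)
        if n_r == 0:
            out.extend([0.0] * 5)
            continue
        for q in _QUANT:
            idx = 1 if q == 0.0 else math.ceil(q * n_r)
            out.append(positions[idx - 1] / n * 100.0)
    return out


def compute_ctd(record: ProteinRecord) -> np.ndarray:
    if len(record) < 2:
        raise ValueError(f"record {record.id!r}: CTD needs at least 2 residues")
    groups = load_ctd_groups()
    blocks: list[float] = []
    for prop in CTD_PROPERTIES:
        enc = encode_groups(record.sequence, groups[prop])
        blocks.extend(_property_block(enc))
    return np.array(blocks)
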