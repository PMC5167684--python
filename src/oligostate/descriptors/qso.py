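"""Sequence-order-coupling numbers and quasi-sequence-order (QSO) descriptors.

Built from a residue-pair distance matrix D. The d-th sequence-order-coupling
number is

    tau_d = sum_{i=1}^{N-d} D(R_i, R_{i+d})^2,   d = 1..30,

computed under each of two distance matrices (a physicochemical matrix and
the Grantham chemical distance matrix), giving 60 coupling numbers. The 100
quasi-sequence-order values follow, per matrix:

    X_r      = f_r / (sum_s f_s + w * sum_d tau_d)        r = 1..20
    X_{20+d} = w * tau_d / (sum_s f_s + w * sum_d tau_d)  d = 1..30

with f_r the residue frequencies N_r/N and weight w (default 0.5). Class
width: 60 + 2 x 50 = 160.
"""

from __future__ import annotations

import numpy as np

from ..scales import QSO_MATRICES, qso_distance_matrices
from ..sequence_io import ALPHABET, ProteinRecord
from .composition import compute_aac, encode


def qso_names(lag: int = 30) -> tuple[str, ...]:
    names = [f"SOCN.{m}.lag{d}" for m in QSO_MATRICES for d in range(1, lag + 1)]
    for m in QSO_MATRICES:
        names.extend(f"QSO.{m}.aa.{a}" for a in ALPHABET)
        names.extend(f"QSO.{m}.lag{d}" for d in range(1, lag + 1))
    return tuple(names)


QSO_NAMES = qso_names()


def coupling_numbers(codes: np.ndarray, dist: np.ndarray, lag: int) -> np.ndarray:
    """tau_1..tau_lag for one distance matrix."""
    n = len(codes)
    if lag >= n:
        raise ValueError(f"lag {lag} exceeds sequence length {n}")
    taus = np.empty(lag)
    for d in range(1, lag + 1):
        taus[d - 1] = np.sum(dist[codes[:-d], codes[d:]] ** 2)
    return taus


def compute_qso(
    record: ProteinRecord,
    lag: int = 30,
    w: float = 0.5,
    matrices: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    if matrices is None:
        matrices = qso_distance_matrices()
    codes = encode(record)
    if lag >= len(codes):
        raise ValueError(f"record {record.id!r}: lag {lag} exceeds sequence length {len(codes)}")
    freqs = compute_aac(record)
    taus = {name: coupling_numbers(codes, dist, lag) for name, dist in matrices.items()}
    parts = [taus[name] for name in matrices]  # 60 coupling numbers
    for name in matrices:
        denom = freqs.sum() + w * taus[name].sum()
        parts.append(freqs / denom)
        parts.append(w * taus[name] / denom)
    return np.concatenate(parts)
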