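"""Pseudo amino acid composition, type 1 (PseAAC) and type 2 (APseAAC).

Both types extend the 20 composition frequencies with sequence-order terms
derived from standardized hydrophobicity (H1), hydrophilicity (H2) and, for
type 1, side-chain mass (M). Scales are standardized over the 20 residues
(zero mean, unit population SD).

Type 1 uses the three-term squared-difference correlation

    theta(i, j) = [ (H1_i - H1_j)^2 + (H2_i - H2_j)^2 + (M_i - M_j)^2 ] / 3
    tau_k = (1/(N-k)) sum_{i=1}^{N-k} theta(i, i+k),  k = 1..lambda

and emits 20 + lambda = 50 components. Type 2 (amphiphilic) uses the
hydrophobicity/hydrophilicity products

    H1_{i,j} = H1(i) * H1(j),   H2_{i,j} = H2(i) * H2(j)
    tau_{2k-1} = (1/(N-k)) sum H1_{i,i+k},  tau_{2k} = (1/(N-k)) sum H2_{i,i+k}

for k = 1..lambda, emitting 20 + 2*lambda = 80 components. In both, with
weight w (default 0.5) and frequencies f_r = N_r/N,

    P_c      = f_c / (sum_r f_r + w * sum_j tau_j)       c = 1..20
    P_{20+u} = w * tau_u / (sum_r f_r + w * sum_j tau_j)

so each full vector sums to 1. The combined class is 130 wide.
"""

from __future__ import annotations

import numpy as np

from ..scales import load_pseaac_scales
from ..sequence_io import ALPHABET, ProteinRecord
from .composition import compute_aac, encode


def pseaac_names(lam: int = 30) -> tuple[str, ...]:
    return tuple(
        [f"PseAAC.{a}" for a in ALPHABET] + [f"PseAAC.lambda{k}" for k in range(1, lam + 1)]
    )


def apseaac_names(lam: int = 30) -> tuple[str, ...]:
    return tuple(
        [f"APseAAC.{a}" for a in ALPHABET] + [f"APseAAC.tau{u}" for u in range(1, 2 * lam + 1)]
    )


PSEAAC_NAMES = pseaac_names()
APSEAAC_NAMES = apseaac_names()


def _profiles(record: ProteinRecord) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    scales = load_pseaac_scales()
    codes = encode(record)
    h1 = scales["hydrophobicity"].as_array()[codes]
    h2 = scales["hydrophilicity"].as_array()[codes]
    m = scales["side_chain_mass"].as_array()[codes]
    return h1, h2, m


def compute_pseaac(record: ProteinRecord, lam: int = 30, w: float = 0.5) -> np.ndarray:
    """Type-1 pseudo amino acid composition: 20 + lam components."""
    n = len(record)
    if lam >= n:
        raise ValueError(f"record {record.id!r}: lambda {lam} exceeds sequence length {n}")
    h1, h2, m = _profiles(record)
    taus = np.empty(lam)
    for k in range(1, lam + 1):
        theta = ((h1[:-k] - h1[k:]) ** 2 + (h2[:-k] - h2[k:]) ** 2 + (m[:-k] - m[k:]) ** 2) / 3.0
        taus[k - 1] = theta.mean()
    freqs = compute_aac(record)
    denom = freqs.sum() + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])


def compute_apseaac(record: ProteinRecord, lam: int = 30, w: float = 0.5) -> np.ndarray:
    """Type-2 (amphiphilic) pseudo amino acid composition: 20 + 2*lam components."""
    n = len(record)
    if lam >= n:
        raise ValueError(f"record {record.id!r}: lambda {lam} exceeds sequence length {n}")
    h1, h2, _ = _profiles(record)
    taus = np.empty(2 * lam)
    for k in range(1, lam + 1):
        taus[2 * k - 2] = np.mean(h1[:-k] * h1[k:])
        taus[2 * k - 1] = np.mean(h2[:-k] * h2[k:])
    freqs = compute_aac(record)
    denom = freqs.sum() + w * taus.sum()
    return np.concatenate([freqs / denom, w * taus / denom])
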