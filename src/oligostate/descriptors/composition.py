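"""Amino acid, dipeptide and tripeptide composition (AAC/DPC/TPC).

Overlapping k-mer frequencies over the 20-letter alphabet:

    f(r)     = N_r / N          20 values
    f(r,s)   = N_rs / (N - 1)   400 values
    f(r,s,t) = N_rst / (N - 2)  8000 values

Each block sums to 1. Together they form the 8420-wide AAC/DPC/TPC class.
"""

from __future__ import annotations

import itertools

import numpy as np

from ..sequence_io import ALPHABET, ProteinRecord

_INDEX = {a: i for i, a in enumerate(ALPHABET)}

AAC_NAMES = tuple(f"AAC.{a}" for a in ALPHABET)
DPC_NAMES = tuple(f"DPC.{a}{b}" for a, b in itertools.product(ALPHABET, repeat=2))
TPC_NAMES = tuple(f"TPC.{a}{b}{c}" for a, b, c in itertools.product(ALPHABET, repeat=3))


def encode(record: ProteinRecord) -> np.ndarray:
    """Sequence as integer codes 0..19 in canonical alphabet order."""
    return np.fromiter((_INDEX[ch] for ch in record.sequence), dtype=np.int64, count=len(record))


def compute_aac(record: ProteinRecord) -> np.ndarray:
    codes = encode(record)
    return np.bincount(codes, minlength=20) / len(codes)


def compute_dpc(record: ProteinRecord) -> np.ndarray:
    codes = encode(record)
    n = len(codes)
    if n < 2:
        raise ValueError(f"record {record.id!r}: sequence too short for dipeptides (N={n})")
    pairs = codes[:-1] * 20 + codes[1:]
    return np.bincount(pairs, minlength=400) / (n - 1)


def compute_tpc(record: ProteinRecord) -> np.ndarray:
    codes = encode(record)
    n = len(codes)
    if n < 3:
        raise ValueError(f"record {record.id!r}: sequence too short for tripeptides (N={n})")
    triples = (codes[:-2] * 20 + codes[1:-1]) * 20 + codes[2:]
    return np.bincount(triples, minlength=8000) / (n - 2)


def kmer_frequency(record: ProteinRecord, kmer: str) -> float:
    """Frequency of one named k-mer (k = 1, 2 or 3), counting overlaps.

    This is the single-column path behind top-k production mode: the value
    equals the corresponding column of the full AAC/DPC/TPC block without
    materializing it.
    """
    k = len(kmer)
    if k not in (1, 2, 3) or any(ch not in _INDEX for ch in kmer):
        raise ValueError(f"not a valid amino acid k-mer: {kmer!r}")
    seq = record.sequence
    n = len(seq)
    if n < k:
        raise ValueError(f"record {record.id!r}: sequence shorter than k-mer {kmer!r}")
    count = sum(1 for i in range(n - k + 1) if seq[i : i + k] == kmer)
    return count / (n - k + 1)
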