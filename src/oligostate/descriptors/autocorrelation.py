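"""Moreau-Broto, Moran and Geary autocorrelation descriptors.

Each descriptor correlates a physicochemical property profile P_1..P_N with a
lagged copy of itself, for lags d = 1..30 over eight AAindex scales
(8 x 30 = 240 values per kind, 720 for the class).

With standardized property values (zero mean, unit population SD over the 20
residues):

    normalized Moreau-Broto:  AC(d) = [ sum_{i=1}^{N-d} P_i P_{i+d} ] / (N - d)
    Moran:   I(d) = [ (1/(N-d)) sum (P_i - Pbar)(P_{i+d} - Pbar) ]
                    / [ (1/N) sum (P_i - Pbar)^2 ]
    Geary:   C(d) = [ (1/(2(N-d))) sum (P_i - P_{i+d})^2 ]
                    / [ (1/(N-1)) sum (P_i - Pbar)^2 ]

where Pbar is the mean of the property along the sequence. When the property
profile has zero variance along the sequence (e.g. a homopolymer) the Moran
and Geary ratios are defined as 0 so such sequences remain scorable.
"""

from __future__ import annotations

import logging

import numpy as np

from ..scales import AAINDEX_IDS, PropertyScale, load_aaindex_scales
from ..sequence_io import ProteinRecord
from .composition import encode

logger = logging.getLogger(__name__)

KINDS = ("moreau_broto", "moran", "geary")
_KIND_LABEL = {"moreau_broto": "MoreauBroto", "moran": "Moran", "geary": "Geary"}


def autocorrelation_names(kind: str, scale_ids=AAINDEX_IDS, lag: int = 30) -> tuple[str, ...]:
    label = _KIND_LABEL[kind]
    return tuple(f"{label}.{sid}.lag{d}" for sid in scale_ids for d in range(1, lag + 1))


def _profile_stats(p: np.ndarray):
    pbar = p.mean()
    dev = p - pbar
    return pbar, dev, float(np.dot(dev, dev))


def autocorrelation_profile(p: np.ndarray, kind: str, lag: int) -> np.ndarray:
    """One kind of autocorrelation for a single property profile ``p``."""
    n = len(p)
    if lag >= n:
        raise ValueError(f"lag {lag} exceeds sequence length {n}")
    _, dev, ss = _profile_stats(p)
    out = np.empty(lag)
    if kind == "moreau_broto":
        for d in range(1, lag + 1):
            out[d - 1] = np.dot(p[:-d], p[d:]) / (n - d)
        return out
    if ss <= 1e-12 * max(1, n):
        logger.warning("zero property variance along sequence; %s set to 0", kind)
        out.fill(0.0)
        return out
    if kind == "moran":
        denom = ss / n
        for d in range(1, lag + 1):
            out[d - 1] = (np.dot(dev[:-d], dev[d:]) / (n - d)) / denom
        return out
    if kind == "geary":
        denom = ss / (n - 1)
        for d in range(1, lag + 1):
            diff = p[:-d] - p[d:]
            out[d - 1] = (np.dot(diff, diff) / (2 * (n - d))) / denom
        return out
    raise ValueError(f"unknown autocorrelation kind {kind!r}")


def compute_autocorrelation(
    record: ProteinRecord,
    kind: str,
    scales: dict[str, PropertyScale] | None = None,
    lag: int = 30,
) -> np.ndarray:
    """240-vector (8 scales x ``lag`` lags) of one autocorrelation kind."""
    if kind not in KINDS:
        raise ValueError(f"unknown autocorrelation kind {kind!r}")
    if scales is None:
        scales = load_aaindex_scales()
    codes = encode(record)
    if lag >= len(codes):
        raise ValueError(
            f"record {record.id!r}: lag {lag} exceeds sequence length {len(codes)}"
        )
    blocks = []
    for sid, scale in scales.items():
        p = scale.as_array(standardized=True)[codes]
        blocks.append(autocorrelation_profile(p, kind, lag))
    return np.concatenate(blocks)
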