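"""Independent naive-loop reference implementations of every descriptor
family, written directly from the defining formulas with plain Python loops.
They share only the packaged reference tables (scales, groupings, matrices)
with the library — never its computation paths."""

from __future__ import annotations

import itertools
import math

from oligostate.scales import (
    CTD_PROPERTIES,
    load_aaindex_scales,
    load_ctd_groups,
    load_ctriad_classes,
    load_pseaac_scales,
    qso_distance_matrices,
)
from oligostate.sequence_io import ALPHABET

AA = list(ALPHABET)
AA_INDEX = {a: i for i, a in enumerate(AA)}


def oracle_aac(seq: str) -> list[float]:
    n = len(seq)
    return [sum(1 for ch in seq if ch == a) / n for a in AA]


def oracle_dpc(seq: str) -> list[float]:
    n = len(seq)
    out = []
    for a, b in itertools.product(AA, repeat=2):
        count = sum(1 for i in range(n - 1) if seq[i] == a and seq[i + 1] == b)
        out.append(count / (n - 1))
    return out


def oracle_tpc(seq: str) -> list[float]:
    n = len(seq)
    counts = {}
    for i in range(n - 2):
        counts[seq[i : i + 3]] = counts.get(seq[i : i + 3], 0) + 1
    return [counts.get(a + b + c, 0) / (n - 2) for a, b, c in itertools.product(AA, repeat=3)]


def _standardized(values: dict[str, float]) -> dict[str, float]:
    mean = sum(values.values()) / 20
    sd = math.sqrt(sum((v - mean) ** 2 for v in values.values()) / 20)
    return {a: (v - mean) / sd for a, v in values.items()}


def oracle_autocorrelation(seq: str, lag: int = 30) -> list[float]:
    """Moreau-Broto, then Moran, then Geary blocks (8 scales x lag each)."""
    n = len(seq)
    scales = load_aaindex_scales()
    blocks = {"moreau_broto": [], "moran": [], "geary": []}
    for sid, scale in scales.items():
        std = _standardized(scale.raw_values)
        p = [std[ch] for ch in seq]
        pbar = sum(p) / n
        ss = sum((v - pbar) ** 2 for v in p)
        for d in range(1, lag + 1):
            blocks["moreau_broto"].append(
                sum(p[i] * p[i + d] for i in range(n - d)) / (n - d)
            )
        for d in range(1, lag + 1):
            if ss == 0:
                blocks["moran"].append(0.0)
                continue
            num = sum((p[i] - pbar) * (p[i + d] - pbar) for i in range(n - d)) / (n - d)
            blocks["moran"].append(num / (ss / n))
        for d in range(1, lag + 1):
            if ss == 0:
                blocks["geary"].append(0.0)
                continue
            num = sum((p[i] - p[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
            blocks["geary"].append(num / (ss / (n - 1)))
    return blocks["moreau_broto"] + blocks["moran"] + blocks["geary"]


def oracle_ctd(seq: str) -> list[float]:
    n = len(seq)
    groups = load_ctd_groups()
    out: list[float] = []
    for prop in CTD_PROPERTIES:
        g1, g2, g3 = groups[prop]
        enc = [1 if ch in g1 else 2 if ch in g2 else 3 for ch in seq]
        for r in (1, 2, 3):
            out.append(sum(1 for e in enc if e == r) / n)
        for r, s in ((1, 2), (1, 3), (2, 3)):
            count = sum(
                1
                for i in range(n - 1)
                if (enc[i] == r and enc[i + 1] == s) or (enc[i] == s and enc[i + 1] == r)
            )
            out.append(count / (n - 1))
        for r in (1, 2, 3):
            positions = [i + 1 for i, e in enumerate(enc) if e == r]
            if not positions:
                out.extend([0.0] * 5)
                continue
            n_r = len(positions)
            for q in (0.0, 0.25, 0.5, 0.75, 1.0):
                idx = 1 if q == 0.0 else math.ceil(q * n_r)
                out.append(positions[idx - 1] / n * 100.0)
    return out


def oracle_ctriad(seq: str) -> list[float]:
    mapping = load_ctriad_classes()
    counts = {}
    for i in range(len(seq) - 2):
        key = (mapping[seq[i]], mapping[seq[i + 1]], mapping[seq[i + 2]])
        counts[key] = counts.get(key, 0) + 1
    vmax = max(counts.values())
    return [
        counts.get((a, b, c), 0) / vmax
        for a, b, c in itertools.product(range(1, 8), repeat=3)
    ]


def oracle_qso(seq: str, lag: int = 30, w: float = 0.5) -> list[float]:
    n = len(seq)
    mats = qso_distance_matrices()
    taus = {}
    for name, mat in mats.items():
        taus[name] = [
            sum(mat[AA_INDEX[seq[i]], AA_INDEX[seq[i + d]]] ** 2 for i in range(n - d))
            for d in range(1, lag + 1)
        ]
    out = []
    for name in mats:
        out.extend(taus[name])
    freqs = oracle_aac(seq)
    for name in mats:
        denom = sum(freqs) + w * sum(taus[name])
        out.extend(f / denom for f in freqs)
        out.extend(w * t / denom for t in taus[name])
    return out


def oracle_pseaac(seq: str, lam: int = 30, w: float = 0.5) -> list[float]:
    n = len(seq)
    scales = load_pseaac_scales()
    h1 = _standardized(scales["hydrophobicity"].raw_values)
    h2 = _standardized(scales["hydrophilicity"].raw_values)
    m = _standardized(scales["side_chain_mass"].raw_values)
    taus = []
    for k in range(1, lam + 1):
        theta = [
            (
                (h1[seq[i]] - h1[seq[i + k]]) ** 2
                + (h2[seq[i]] - h2[seq[i + k]]) ** 2
                + (m[seq[i]] - m[seq[i + k]]) ** 2
            )
            / 3.0
            for i in range(n - k)
        ]
        taus.append(sum(theta) / (n - k))
    freqs = oracle_aac(seq)
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


def oracle_apseaac(seq: str, lam: int = 30, w: float = 0.5) -> list[float]:
    n = len(seq)
    scales = load_pseaac_scales()
    h1 = _standardized(scales["hydrophobicity"].raw_values)
    h2 = _standardized(scales["hydrophilicity"].raw_values)
    taus = []
    for k in range(1, lam + 1):
        taus.append(sum(h1[seq[i]] * h1[seq[i + k]] for i in range(n - k)) / (n - k))
        taus.append(sum(h2[seq[i]] * h2[seq[i + k]] for i in range(n - k)) / (n - k))
    # tau order in the vector is tau_1..tau_2lam i.e. alternating H1/H2 by lag
    freqs = oracle_aac(seq)
    denom = sum(freqs) + w * sum(taus)
    return [f / denom for f in freqs] + [w * t / denom for t in taus]


ORACLES = {
    "aac_dpc_tpc": lambda s: oracle_aac(s) + oracle_dpc(s) + oracle_tpc(s),
    "autocorrelation": oracle_autocorrelation,
    "ctd": oracle_ctd,
    "ctriad": oracle_ctriad,
    "qso": oracle_qso,
    "pseaac": lambda s: oracle_pseaac(s) + oracle_apseaac(s),
}
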