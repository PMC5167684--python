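"""Packaged physicochemical reference data and their loaders.

All reference tables ship as plain TSV under ``oligostate/data`` so they are
auditable: eight AAindex property scales for the autocorrelation descriptors,
the three Chou scales for pseudo amino acid composition, the Dubchak three-group
encodings for CTD, the Shen seven-class alphabet for conjoint triads, and the
Grantham composition/polarity/volume table from which the Grantham chemical
distance matrix is reconstructed.

Scales are standardized over the 20 residues with the population standard
deviation (divisor 20), the convention required for the "normalized"
autocorrelation and pseudo-composition forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .sequence_io import ALPHABET

#: AAindex accessions of the eight autocorrelation scales, in canonical order:
#: normalized average hydrophobicity, average flexibility, polarizability,
#: free energy of solution in water, accessible surface area in tripeptide,
#: residue volume, steric parameter, relative mutability.
AAINDEX_IDS = (
    "CIDH920105",
    "BHAR880101",
    "CHAM820101",
    "CHAM820102",
    "CHOC760101",
    "BIGC670101",
    "CHAM810101",
    "DAYM780201",
)

#: CTD properties in canonical order.
CTD_PROPERTIES = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "secondary_structure",
    "solvent_accessibility",
)


@dataclass(frozen=True)
class PropertyScale:
    """A 20-value physicochemical scale keyed by an AAindex-style identifier.

    ``standardized_values`` has zero mean and unit population SD over the 20
    residues (within 1e-9).
    """

    aaindex_id: str
    raw_values: dict[str, float]

    def __post_init__(self) -> None:
        if sorted(self.raw_values) != sorted(ALPHABET):
            raise ValueError(f"scale {self.aaindex_id}: needs exactly the 20 canonical residues")

    @property
    def standardized_values(self) -> dict[str, float]:
        vals = np.array([self.raw_values[a] for a in ALPHABET], dtype=float)
        std = standardize(vals)
        return dict(zip(ALPHABET, std))

    def as_array(self, standardized: bool = True) -> np.ndarray:
        """Values ordered by the canonical alphabet."""
        vals = np.array([self.raw_values[a] for a in ALPHABET], dtype=float)
        return standardize(vals) if standardized else vals


def standardize(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-population-SD transform over the 20 residues."""
    v = np.asarray(values, dtype=float)
    sd = v.std()  # population SD, divisor 20
    if sd == 0:
        raise ValueError("cannot standardize a constant scale")
    return (v - v.mean()) / sd


def _read_tsv(name: str) -> list[list[str]]:
    text = resources.files("oligostate.data").joinpath(name).read_text()
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def load_aaindex_scales() -> dict[str, PropertyScale]:
    """The eight packaged AAindex scales, keyed by accession."""
    rows = _read_tsv("aaindex_scales.tsv")
    header = rows[0]
    ids = header[1:]
    per_scale: dict[str, dict[str, float]] = {i: {} for i in ids}
    for row in rows[1:]:
        residue = row[0]
        for sid, val in zip(ids, row[1:]):
            per_scale[sid][residue] = float(val)
    scales = {sid: PropertyScale(sid, vals) for sid, vals in per_scale.items()}
    if tuple(scales) != AAINDEX_IDS:
        raise RuntimeError("packaged AAindex scales out of sync with AAINDEX_IDS")
    return scales


@lru_cache(maxsize=None)
def load_pseaac_scales() -> dict[str, PropertyScale]:
    """Hydrophobicity, hydrophilicity and side-chain mass for PseAAC."""
    rows = _read_tsv("pseaac_scales.tsv")
    names = rows[0][1:]
    per: dict[str, dict[str, float]] = {n: {} for n in names}
    for row in rows[1:]:
        for name, val in zip(names, row[1:]):
            per[name][row[0]] = float(val)
    return {n: PropertyScale(n, vals) for n, vals in per.items()}


@lru_cache(maxsize=None)
def load_ctd_groups() -> dict[str, tuple[str, str, str]]:
    """Per CTD property, the residue membership of groups 1-3."""
    groups: dict[str, tuple[str, str, str]] = {}
    for row in _read_tsv("ctd_groups.tsv")[1:]:
        prop, g1, g2, g3 = row
        merged = g1 + g2 + g3
        if sorted(merged) != sorted(ALPHABET):
            raise RuntimeError(f"CTD property {prop}: groups do not partition the alphabet")
        groups[prop] = (g1, g2, g3)
    if tuple(groups) != CTD_PROPERTIES:
        raise RuntimeError("packaged CTD groups out of sync with CTD_PROPERTIES")
    return groups


@lru_cache(maxsize=None)
def load_ctriad_classes() -> dict[str, int]:
    """Residue -> conjoint-triad class (1..7)."""
    mapping: dict[str, int] = {}
    for row in _read_tsv("ctriad_classes.tsv")[1:]:
        cls = int(row[0])
        for residue in row[1]:
            mapping[residue] = cls
    if sorted(mapping) != sorted(ALPHABET):
        raise RuntimeError("conjoint triad classes do not cover the alphabet")
    return mapping


@lru_cache(maxsize=None)
def grantham_distance_matrix(normalized: bool = True) -> np.ndarray:
    """The 20x20 Grantham chemical distance matrix, alphabet-ordered.

    Reconstructed from the packaged composition/polarity/volume table with
    Grantham's formula (alpha=1.833, beta=0.1018, gamma=0.000399; scaled so
    the mean over the 190 residue pairs is 100). ``normalized=True`` divides
    by the maximum entry so distances lie in [0, 1], keeping the
    quasi-sequence-order coupling terms on a scale comparable to composition.
    """
    rows = _read_tsv("grantham_properties.tsv")[1:]
    table = {r[0]: (float(r[1]), float(r[2]), float(r[3])) for r in rows}
    c = np.array([table[a][0] for a in ALPHABET])
    p = np.array([table[a][1] for a in ALPHABET])
    v = np.array([table[a][2] for a in ALPHABET])
    alpha, beta, gamma = 1.833, 0.1018, 0.000399
    sq = (
        alpha * (c[:, None] - c[None, :]) ** 2
        + beta * (p[:, None] - p[None, :]) ** 2
        + gamma * (v[:, None] - v[None, :]) ** 2
    )
    raw = np.sqrt(sq)
    off = raw[np.triu_indices(20, k=1)]
    mat = raw * (100.0 / off.mean())
    if normalized:
        mat = mat / mat.max()
    return mat


@lru_cache(maxsize=None)
def synthetic_physchem_distance_matrix() -> np.ndarray:
    """A synthetic physicochemical residue distance matrix, alphabet-ordered.

    This is a SYNTHETIC stand-in for the Schneider-Wrede distance matrix that
    quasi-sequence-order descriptors are classically paired with: the
    Euclidean distance between residues in the plane of their standardized
    hydrophobicity and hydrophilicity values, normalized to [0, 1]. It
    preserves the construction (a symmetric, zero-diagonal physicochemical
    dissimilarity) without reproducing the published numbers, which are not
    packaged here.
    """
    scales = load_pseaac_scales()
    h1 = scales["hydrophobicity"].as_array()
    h2 = scales["hydrophilicity"].as_array()
    mat = np.sqrt((h1[:, None] - h1[None, :]) ** 2 + (h2[:, None] - h2[None, :]) ** 2)
    return mat / mat.max()


#: Names and loaders of the two QSO distance matrices, in canonical order.
QSO_MATRICES = ("physchem", "grantham")


def qso_distance_matrices() -> dict[str, np.ndarray]:
    return {
        "physchem": synthetic_physchem_distance_matrix(),
        "grantham": grantham_distance_matrix(),
    }


@lru_cache(maxsize=None)
def load_background_frequencies(kind: str = "uniform") -> np.ndarray:
    """Background residue frequencies for the synthetic generator.

    ``"uniform"`` is 1/20 everywhere; ``"uniprot"`` loads Swiss-Prot average
    composition from the packaged table.
    """
    if kind == "uniform":
        return np.full(20, 1.0 / 20)
    if kind == "uniprot":
        rows = _read_tsv("uniprot_frequencies.tsv")[1:]
        table = {r[0]: float(r[1]) for r in rows}
        freqs = np.array([table[a] for a in ALPHABET])
        return freqs / freqs.sum()
    raise ValueError(f"unknown background {kind!r}")
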