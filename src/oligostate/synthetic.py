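"""Labelled synthetic protein sets with controllable class signal.

The generator emulates the shape of a curated fluorescent-protein data set —
a few hundred sequences of FP-like length (220-240 residues) labelled monomer
or oligomer — so the whole pipeline is testable without external data. Two
signal types inject a class difference whose strength is dialled in [0, 1]:

* ``composition_bias``: oligomer sequences are drawn with hydrophobic-residue
  enrichment (oligomeric interfaces are predominantly hydrophobic), monomers
  from the unmodified background;
* ``motif_insertion``: oligomer sequences carry planted copies of short
  motifs (RMY, LI — the k-mers informative for oligomerization), monomers
  are scrubbed of them.

At ``strength=0`` (or ``signal="none"``) the two classes are identically
distributed. ``make_duplicates`` appends near-copies at known identity to
exercise homology reduction with exact expected cluster counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scales import load_background_frequencies
from .sequence_io import ALPHABET, LabelledRecord, ProteinRecord

#: residues treated as hydrophobic for the composition-bias signal
#: (group 3 of the CTD hydrophobicity encoding)
HYDROPHOBIC = "CLVIMFW"

#: tripeptide/dipeptide motifs planted by the motif-insertion signal
MOTIFS = ("RMY", "LI")

SIGNALS = ("composition_bias", "motif_insertion", "none")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set.

    Defaults: 100 sequences per class of length 220-240 (FP-like), moderate
    composition bias (strength 0.5), uniform background composition. Lengths
    must be >= 35 so every descriptor precondition (lag/lambda = 30) holds.
    """

    n_per_class: int = 100
    length_range: tuple[int, int] = (220, 240)
    signal: str = "composition_bias"
    strength: float = 0.5
    seed: int = 0
    background: str = "uniform"

    def __post_init__(self) -> None:
        if self.length_range[0] < 35:
            raise ValueError("minimum length must be >= 35 (descriptor preconditions)")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("invalid length range")
        if self.signal not in SIGNALS:
            raise ValueError(f"unknown signal {self.signal!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be in [0, 1]")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")


def _class_frequencies(spec: FixtureSpec) -> tuple[np.ndarray, np.ndarray]:
    base = load_background_frequencies(spec.background)
    if spec.signal != "composition_bias" or spec.strength == 0:
        return base, base
    weights = np.array([1.0 + 2.0 * spec.strength if a in HYDROPHOBIC else 1.0 for a in ALPHABET])
    oligo = base * weights
    return base, oligo / oligo.sum()


def _draw_sequence(rng: np.random.Generator, length: int, freqs: np.ndarray) -> str:
    codes = rng.choice(20, size=length, p=freqs)
    return "".join(ALPHABET[c] for c in codes)


def _scrub_motifs(seq: str, rng: np.random.Generator, freqs: np.ndarray) -> str:
    """Resample residues until no planted motif occurs by chance."""
    chars = list(seq)
    changed = True
    while changed:
        changed = False
        s = "".join(chars)
        for motif in MOTIFS:
            pos = s.find(motif)
            if pos >= 0:
                chars[pos] = ALPHABET[rng.choice(20, p=freqs)]
                changed = True
    return "".join(chars)


def _plant_motifs(seq: str, rng: np.random.Generator, copies: int) -> str:
    """Overwrite ``copies`` non-overlapping windows with each motif."""
    chars = list(seq)
    taken: set[int] = set()
    for motif in MOTIFS:
        k = len(motif)
        for _ in range(copies):
            for _attempt in range(200):
                start = int(rng.integers(0, len(chars) - k + 1))
                span = set(range(start - 2, start + k + 2))  # pad to avoid overlap joins
                if span.isdisjoint(taken):
                    chars[start : start + k] = motif
                    taken.update(range(start, start + k))
                    break
            else:  # pragma: no cover - virtually impossible at FP lengths
                raise RuntimeError("could not place motif without overlap")
    return "".join(chars)


def generate(spec: FixtureSpec) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Generate labelled records per the fixture spec.

    Returns the records (monomers first, ids ``mono_0001``.../``oligo_0001``...)
    and an id -> label mapping. Fixed seed gives identical output.
    """
    rng = np.random.default_rng(spec.seed)
    mono_freqs, oligo_freqs = _class_frequencies(spec)
    motif_mode = spec.signal == "motif_insertion" and spec.strength > 0
    copies = int(np.ceil(3 * spec.strength)) if motif_mode else 0

    records: list[ProteinRecord] = []
    labels: dict[str, str] = {}
    lo, hi = spec.length_range
    for label, freqs, prefix in (
        ("monomer", mono_freqs, "mono"),
        ("oligomer", oligo_freqs, "oligo"),
    ):
        for i in range(spec.n_per_class):
            length = int(rng.integers(lo, hi + 1))
            seq = _draw_sequence(rng, length, freqs)
            if motif_mode:
                if label == "oligomer":
                    seq = _plant_motifs(seq, rng, copies)
                else:
                    seq = _scrub_motifs(seq, rng, freqs)
            rid = f"{prefix}_{i + 1:04d}"
            records.append(ProteinRecord(id=rid, sequence=seq))
            labels[rid] = label
    return records, labels


def as_labelled(records: list[ProteinRecord], labels: dict[str, str]) -> list[LabelledRecord]:
    return [LabelledRecord(record=r, label=labels[r.id]) for r in records]


def make_duplicates(
    records: list[ProteinRecord], k: int, mutations: int, seed: int = 0
) -> list[ProteinRecord]:
    """Append ``k`` mutated near-copies of every record.

    Each copy differs from its source at exactly ``mutations`` positions
    (substitutions to a different residue), i.e. ungapped identity
    (N - mutations) / N — giving exact expected cluster counts at a chosen
    threshold. Copies are named ``<id>_dup<j>``.
    """
    rng = np.random.default_rng(seed)
    out = list(records)
    for rec in records:
        n = len(rec)
        if mutations >= n:
            raise ValueError(f"mutations must be < sequence length ({n})")
        for j in range(1, k + 1):
            chars = list(rec.sequence)
            positions = rng.choice(n, size=mutations, replace=False)
            for pos in positions:
                current = chars[pos]
                choices = [a for a in ALPHABET if a != current]
                chars[pos] = choices[int(rng.integers(0, 19))]
            out.append(ProteinRecord(id=f"{rec.id}_dup{j}", sequence="".join(chars)))
    return out
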