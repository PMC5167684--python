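"""Descriptor class assembly: per-sequence vectors into feature tables.

A feature table is a :class:`pandas.DataFrame` with sequence ids as the index
and descriptor names as columns, in a deterministic canonical order. The six
canonical classes and their widths:

    aac_dpc_tpc      8420   (20 AAC + 400 DPC + 8000 TPC)
    autocorrelation   720   (3 kinds x 8 AAindex scales x 30 lags)
    ctd               147   (7 properties x (3 C + 3 T + 15 D))
    ctriad            343   (7^3 class triads)
    qso               160   (60 coupling numbers + 2 x 50 QSO values)
    pseaac            130   (50 type-1 + 80 amphiphilic)

The convenience subsets ``aac``, ``dpc`` and ``tpc`` expose individual
composition blocks for cheap reduced-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..sequence_io import ProteinRecord
from . import composition as comp
from .autocorrelation import KINDS, autocorrelation_names, compute_autocorrelation
from .ctd import CTD_NAMES, compute_ctd
from .ctriad import CTRIAD_NAMES, compute_ctriad
from .pseaac import apseaac_names, compute_apseaac, compute_pseaac, pseaac_names
from .qso import compute_qso, qso_names


@dataclass(frozen=True)
class DescriptorConfig:
    """Tunable descriptor parameters.

    ``lag`` is the maximum autocorrelation/sequence-order lag and ``lam`` the
    pseudo-composition lambda; both default to 30 (every scored sequence must
    be longer than either). ``weight`` is the QSO/PseAAC weighting factor w.
    ``selected_features`` switches production mode: only the named features
    are computed.
    """

    lag: int = 30
    lam: int = 30
    weight: float = 0.5
    selected_features: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.lag < 1 or self.lam < 1:
            raise ValueError("lag and lambda must be positive")


DEFAULT_CONFIG = DescriptorConfig()

#: Canonical class widths at the default configuration.
CLASS_WIDTHS = {
    "aac_dpc_tpc": 8420,
    "autocorrelation": 720,
    "ctd": 147,
    "ctriad": 343,
    "qso": 160,
    "pseaac": 130,
}

CLASS_NAMES = tuple(CLASS_WIDTHS)
SUBSET_CLASSES = ("aac", "dpc", "tpc")

#: Minimum sequence length per class (lag/lambda bounds are checked at
#: compute time against the configured values).
_MIN_LENGTH = {"aac_dpc_tpc": 3, "ctd": 2, "ctriad": 3, "aac": 1, "dpc": 2, "tpc": 3}


def class_feature_names(class_name: str, config: DescriptorConfig = DEFAULT_CONFIG) -> tuple[str, ...]:
    """Canonical column order of one descriptor class."""
    if class_name == "aac_dpc_tpc":
        return comp.AAC_NAMES + comp.DPC_NAMES + comp.TPC_NAMES
    if class_name == "autocorrelation":
        names: tuple[str, ...] = ()
        for kind in KINDS:
            names += autocorrelation_names(kind, lag=config.lag)
        return names
    if class_name == "ctd":
        return CTD_NAMES
    if class_name == "ctriad":
        return CTRIAD_NAMES
    if class_name == "qso":
        return qso_names(config.lag)
    if class_name == "pseaac":
        return pseaac_names(config.lam) + apseaac_names(config.lam)
    if class_name == "aac":
        return comp.AAC_NAMES
    if class_name == "dpc":
        return comp.DPC_NAMES
    if class_name == "tpc":
        return comp.TPC_NAMES
    raise ValueError(f"unknown descriptor class {class_name!r}")


def _compute_one(record: ProteinRecord, class_name: str, config: DescriptorConfig) -> np.ndarray:
    min_len = _MIN_LENGTH.get(class_name)
    if min_len is not None and len(record) < min_len:
        raise ValueError(
            f"record {record.id!r}: length {len(record)} below minimum {min_len} "
            f"for class {class_name!r}"
        )
    if class_name == "aac_dpc_tpc":
        return np.concatenate(
            [comp.compute_aac(record), comp.compute_dpc(record), comp.compute_tpc(record)]
        )
    if class_name == "autocorrelation":
        return np.concatenate(
            [compute_autocorrelation(record, kind, lag=config.lag) for kind in KINDS]
        )
    if class_name == "ctd":
        return compute_ctd(record)
    if class_name == "ctriad":
        return compute_ctriad(record)
    if class_name == "qso":
        return compute_qso(record, lag=config.lag, w=config.weight)
    if class_name == "pseaac":
        return np.concatenate(
            [
                compute_pseaac(record, lam=config.lam, w=config.weight),
                compute_apseaac(record, lam=config.lam, w=config.weight),
            ]
        )
    if class_name == "aac":
        return comp.compute_aac(record)
    if class_name == "dpc":
        return comp.compute_dpc(record)
    if class_name == "tpc":
        return comp.compute_tpc(record)
    raise ValueError(f"unknown descriptor class {class_name!r}")


def compute_class(
    records: list[ProteinRecord],
    class_name: str,
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Feature table of one descriptor class for a record collection."""
    names = class_feature_names(class_name, config)
    rows = np.empty((len(records), len(names)))
    for i, rec in enumerate(records):
        try:
            rows[i] = _compute_one(rec, class_name, config)
        except ValueError as exc:
            raise ValueError(f"descriptor class {class_name!r}: {exc}") from exc
    return pd.DataFrame(rows, index=[r.id for r in records], columns=list(names))


def _resolve_selected_name(name: str) -> tuple[str, str]:
    """Map a selected-feature name onto (class, canonical column name).

    Bare residue strings of length 1-3 (the form feature-usage rankings print
    for composition features, e.g. ``RMY`` or ``LI``) are accepted alongside
    fully qualified names like ``TPC.RMY``.
    """
    bare = name
    if "." not in name and 1 <= len(name) <= 3:
        prefix = {1: "AAC", 2: "DPC", 3: "TPC"}[len(name)]
        bare = f"{prefix}.{name}"
    if bare.split(".")[0] in ("AAC", "DPC", "TPC"):
        kmer = bare.split(".", 1)[1]
        comp.kmer_frequency  # validated at compute time
        return "composition", bare
    for cls in ("autocorrelation", "ctd", "ctriad", "qso", "pseaac"):
        if bare in class_feature_names(cls):
            return cls, bare
    raise ValueError(f"unknown feature name {name!r}")


def compute_selected(
    records: list[ProteinRecord],
    selected_features: list[str] | tuple[str, ...],
    config: DescriptorConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Compute only the named features (production / top-k mode).

    Composition features (named dipeptides/tripeptides) are computed one
    column at a time without materializing the 8420-wide block; features of
    the other, narrow classes are computed via their class and projected.
    Values are identical to the corresponding columns of
    :func:`compute_class`.
    """
    if not selected_features:
        raise ValueError("selected_features must be non-empty")
    resolved = [_resolve_selected_name(n) for n in selected_features]
    out = pd.DataFrame(index=[r.id for r in records])
    cached: dict[str, pd.DataFrame] = {}
    for (cls, canonical), requested in zip(resolved, selected_features):
        if cls == "composition":
            kmer = canonical.split(".", 1)[1]
            try:
                out[canonical] = [comp.kmer_frequency(r, kmer) for r in records]
            except ValueError as exc:
                raise ValueError(f"unknown feature name {requested!r}") from exc
        else:
            if cls not in cached:
                cached[cls] = compute_class(records, cls, config)
            out[canonical] = cached[cls][canonical]
    return out


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Serialize a feature table to CSV (first column ``id``)."""
    table.to_csv(path, index_label="id")


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="id")
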