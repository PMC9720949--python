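"""Sequence-derived features: CDR charges, lengths, motifs, isoelectric points.

The isoelectric point is computed in the classic proteomics style: the pH
where the Henderson-Hasselbalch net charge over the ionisable side chains
(D, E, C, Y, H, K, R) and the two termini crosses zero, found by bisection.
Raw values are then mapped through affine calibrations fitted on measured
antibody and peptide isoelectric points:

    IEP_antibody = 2.0306 * IEP_raw - 7.8541
    IEP_peptide  = 1.1552 * IEP_raw - 0.8839

The whole-molecule value uses the antibody calibration; the CDR and CDR3
values (computed on the concatenated loop sequences) use the peptide one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import AA_ALPHABET, AntibodyAnnotation, ScFvRecord
from .errors import FeatureError

# Affine calibration constants (pH units per pH unit, pH units).
IEP_ANTIBODY_SLOPE = 2.0306
IEP_ANTIBODY_INTERCEPT = -7.8541
IEP_PEPTIDE_SLOPE = 1.1552
IEP_PEPTIDE_INTERCEPT = -0.8839

# Default side-chain / termini pKa table (editable config; EMBOSS-style
# values in the lineage of the classic sequence-based pI estimators).
DEFAULT_PKA_TABLE: dict[str, float] = {
    "Nterm": 8.6,
    "Cterm": 3.6,
    "C": 8.5,
    "D": 3.9,
    "E": 4.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "Y": 10.1,
}

_POSITIVE_SITES = ("Nterm", "K", "R", "H")
_NEGATIVE_SITES = ("Cterm", "D", "E", "C", "Y")

DEFAULT_MOTIFS = ("G", "Q", "R", "V", "W", "VV", "WW")


class ChargeModel:
    """Base class: maps a residue to its charge contribution."""

    def residue_charge(self, aa: str) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class IntegerChargeModel(ChargeModel):
    """Integer side-chain charges at neutral pH: K,R = +1; D,E = -1; H = 0.

    Termini are ignored (the CDR loops are internal substrings)."""

    charges: Mapping[str, float] = field(
        default_factory=lambda: {
            **{aa: 0.0 for aa in AA_ALPHABET},
            "K": 1.0,
            "R": 1.0,
            "D": -1.0,
            "E": -1.0,
        }
    )

    def residue_charge(self, aa: str) -> float:
        try:
            return self.charges[aa]
        except KeyError:
            raise FeatureError(f"unknown residue {aa!r}") from None


@dataclass(frozen=True)
class HendersonHasselbalchChargeModel(ChargeModel):
    """Fractional side-chain charges at a fixed pH (termini excluded)."""

    ph: float = 7.0
    pka_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PKA_TABLE)
    )

    def residue_charge(self, aa: str) -> float:
        if aa not in AA_ALPHABET:
            raise FeatureError(f"unknown residue {aa!r}")
        if aa in ("K", "R", "H"):
            return 1.0 / (1.0 + 10.0 ** (self.ph - self.pka_table[aa]))
        if aa in ("D", "E", "C", "Y"):
            return -1.0 / (1.0 + 10.0 ** (self.pka_table[aa] - self.ph))
        return 0.0


def cdr_net_charge(cdr_seq: str, model: ChargeModel) -> float:
    """Net charge of a CDR substring in elementary charges (additive)."""
    return float(sum(model.residue_charge(aa) for aa in cdr_seq))


def cdr_lengths(annotation: AntibodyAnnotation) -> dict[str, int]:
    """CDR lengths in residues, heavy+light pooled per loop index."""
    lens = {n: len(annotation.cdr_seq(n)) for n in ("H1", "H2", "H3", "L1", "L2", "L3")}
    out = {
        "cdr1": lens["H1"] + lens["L1"],
        "cdr2": lens["H2"] + lens["L2"],
        "cdr3": lens["H3"] + lens["L3"],
    }
    out["all"] = out["cdr1"] + out["cdr2"] + out["cdr3"]
    return out


def motif_stats(
    region_seq: str, motifs: Iterable[str] = DEFAULT_MOTIFS
) -> dict[str, tuple[int, float]]:
    """Overlapping occurrence count and count-to-length ratio per motif.

    An empty region yields count 0 and ratio 0 for every motif.
    """
    out: dict[str, tuple[int, float]] = {}
    n = len(region_seq)
    for motif in motifs:
        if not motif or set(motif) - AA_ALPHABET:
            raise FeatureError(f"invalid motif {motif!r}")
        if n == 0:
            out[motif] = (0, 0.0)
            continue
        count = sum(
            1
            for i in range(n - len(motif) + 1)
            if region_seq[i: i + len(motif)] == motif
        )
        out[motif] = (count, count / n)
    return out


def _net_charge_at_ph(
    seq: str, ph: float, pka: Mapping[str, float]
) -> float:
    counts = {aa: seq.count(aa) for aa in "CDEHKRY"}
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["Cterm"] - ph))
    for aa in ("K", "R", "H"):
        charge += counts[aa] / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in ("D", "E", "C", "Y"):
        charge -= counts[aa] / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def iep_raw(
    seq: str,
    pka_table: Mapping[str, float] | None = None,
    tol: float = 1e-4,
) -> float:
    """Uncorrected isoelectric point: bisection root of the net-charge
    curve on pH [0, 14]."""
    if not seq:
        raise FeatureError("cannot compute pI of an empty sequence")
    pka = dict(DEFAULT_PKA_TABLE if pka_table is None else pka_table)
    lo, hi = 0.0, 14.0
    f_lo = _net_charge_at_ph(seq, lo, pka)
    f_hi = _net_charge_at_ph(seq, hi, pka)
    if f_lo <= 0.0 or f_hi >= 0.0:
        raise FeatureError("net charge does not change sign on [0, 14]")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _net_charge_at_ph(seq, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class IepResult:
    iep_raw: float
    iep_corrected: float
    correction_kind: str


def iep_corrected(raw: float, kind: str) -> IepResult:
    """Affine calibration of a raw pI to the antibody or peptide scale."""
    if kind == "antibody":
        value = IEP_ANTIBODY_SLOPE * raw + IEP_ANTIBODY_INTERCEPT
    elif kind == "peptide":
        value = IEP_PEPTIDE_SLOPE * raw + IEP_PEPTIDE_INTERCEPT
    else:
        raise ValueError(f"kind must be 'antibody' or 'peptide', got {kind!r}")
    return IepResult(iep_raw=raw, iep_corrected=value, correction_kind=kind)


def compute_iep_panel(
    record: ScFvRecord,
    annotation: AntibodyAnnotation,
    pka_table: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """whole-IEP (antibody calibration), CDR-IEP and CDR3-IEP (peptide
    calibration on the concatenated loop sequences)."""
    whole = iep_corrected(iep_raw(record.sequence, pka_table), "antibody")
    cdr = iep_corrected(iep_raw(annotation.cdr_concat, pka_table), "peptide")
    cdr3 = iep_corrected(iep_raw(annotation.cdr3_concat, pka_table), "peptide")
    return {
        "whole_iep": whole.iep_corrected,
        "cdr_iep": cdr.iep_corrected,
        "cdr3_iep": cdr3.iep_corrected,
    }


# ---------------------------------------------------------------------------
# Feature vector and the F46 registry


@dataclass
class FeatureVector:
    """Ordered named features with per-feature provenance tags."""

    names: list[str]
    values: np.ndarray
    provenance: dict[str, str]
    complete: bool = True

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise FeatureError("names/values length mismatch")
        if len(set(self.names)) != len(self.names):
            raise FeatureError("duplicate feature names")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names)


HYDRO_FIELDS = (
    "vbar", "Ro", "Rg", "Dmax", "axial_ratio", "f_f0", "Dt",
    "Rtrans", "s", "Dr", "Rrot", "tauC", "asphericity",
)

F46_REGISTRY_VERSION = "f46-v1"


def _motif_feature_names() -> list[str]:
    names = []
    for m in ("G", "Q", "R", "V", "W"):
        names += [f"cdr3_{m}_count", f"cdr3_{m}_ratio"]
    names += ["cdr3_VV_count", "cdr3_WW_count"]
    for m in ("G", "Q", "R", "V", "W"):
        names += [f"cdrh3_{m}_count", f"cdrh3_{m}_ratio"]
    return names


def f46_registry() -> list[str]:
    """The default 46-name feature registry.

    4 net charges + 4 lengths + 13 hydrodynamic factors + 3 isoelectric
    points + 22 CDR3/CDR-H3 motif statistics.
    """
    names = [
        "charge_cdr_all", "charge_cdr1", "charge_cdr2", "charge_cdr3",
        "len_cdr_all", "len_cdr1", "len_cdr2", "len_cdr3",
    ]
    names += [f"hydro_{f}" for f in HYDRO_FIELDS]
    names += ["whole_iep", "cdr_iep", "cdr3_iep"]
    names += _motif_feature_names()
    return names


def registry_manifest() -> dict[str, object]:
    return {
        "registry_version": F46_REGISTRY_VERSION,
        "n_features": len(f46_registry()),
        "charge_model": "integer-side-chain",
        "pka_table": DEFAULT_PKA_TABLE,
        "motifs": list(DEFAULT_MOTIFS),
    }


def assemble_f46(
    record: ScFvRecord,
    annotation: AntibodyAnnotation,
    hydro: Mapping[str, float] | None,
    charge_model: ChargeModel | None = None,
    pka_table: Mapping[str, float] | None = None,
) -> FeatureVector:
    """Assemble the 46-feature biochemical panel for one record.

    ``hydro`` is the 13-factor hydrodynamic panel (``None`` when no
    structure is available: the structure block is NaN and the vector is
    flagged incomplete).
    """
    model = charge_model or IntegerChargeModel()
    cdr = {n: annotation.cdr_seq(n) for n in ("H1", "H2", "H3", "L1", "L2", "L3")}
    groups = {
        "all": annotation.cdr_concat,
        "cdr1": cdr["H1"] + cdr["L1"],
        "cdr2": cdr["H2"] + cdr["L2"],
        "cdr3": cdr["H3"] + cdr["L3"],
    }
    values: dict[str, float] = {}
    provenance: dict[str, str] = {}
    for key, seq in groups.items():
        name = "charge_cdr_all" if key == "all" else f"charge_{key}"
        values[name] = cdr_net_charge(seq, model)
        provenance[name] = "sequence"
    lens = cdr_lengths(annotation)
    for key in ("all", "cdr1", "cdr2", "cdr3"):
        name = "len_cdr_all" if key == "all" else f"len_{key}"
        values[name] = float(lens[key])
        provenance[name] = "sequence"

    complete = True
    for fname in HYDRO_FIELDS:
        name = f"hydro_{fname}"
        if hydro is None:
            values[name] = math.nan
            complete = False
        else:
            values[name] = float(hydro[fname])
        provenance[name] = "structure"

    values.update(compute_iep_panel(record, annotation, pka_table))
    for name in ("whole_iep", "cdr_iep", "cdr3_iep"):
        provenance[name] = "sequence"

    cdr3_stats = motif_stats(annotation.cdr3_concat)
    h3_stats = motif_stats(annotation.cdrh3)
    for m in ("G", "Q", "R", "V", "W"):
        values[f"cdr3_{m}_count"] = float(cdr3_stats[m][0])
        values[f"cdr3_{m}_ratio"] = cdr3_stats[m][1]
        values[f"cdrh3_{m}_count"] = float(h3_stats[m][0])
        values[f"cdrh3_{m}_ratio"] = h3_stats[m][1]
    values["cdr3_VV_count"] = float(cdr3_stats["VV"][0])
    values["cdr3_WW_count"] = float(cdr3_stats["WW"][0])
    for name in _motif_feature_names():
        provenance[name] = "sequence"

    registry = f46_registry()
    return FeatureVector(
        names=registry,
        values=np.array([values[n] for n in registry]),
        provenance=provenance,
        complete=complete,
    )
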