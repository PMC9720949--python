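"""Dataset curation, stratified splitting, and a synthetic scFv generator.

The generator emulates the shape of high-throughput FACS polyreactivity
screens of scFv libraries: a fixed human VH/VL scaffold, variable-length
randomised CDR loops joined by a (G4S)3 linker, a roughly 46:54 positive
class balance, and a label planted through a logistic rule on loop
composition (CDR-H3 tryptophan content, CDR2 net charge, CDR1 length) --
the loop properties repeatedly implicated in antibody nonspecificity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import ScFvRecord, VH_TEMPLATE, VL_TEMPLATE
from .errors import SplitError
from .hydro import StructureModel, RESIDUE_MASSES_1
from .seqfeat import IntegerChargeModel, cdr_net_charge

DEFAULT_CLASS_BALANCE = 8867 / 19426  # positive fraction of the reference screen
DEFAULT_LINKER = "GGGGSGGGGSGGGGS"


@dataclass
class Curation:
    """Report of the three-step curation procedure."""

    input_count: int
    removed_duplicates: int
    removed_ambiguous: int
    overhang_pre: str
    overhang_post: str
    final_records: list[ScFvRecord]

    @property
    def final_count(self) -> int:
        return len(self.final_records)

    def to_dict(self) -> dict[str, object]:
        return {
            "input": self.input_count,
            "removed_duplicates": self.removed_duplicates,
            "removed_ambiguous": self.removed_ambiguous,
            "final": self.final_count,
            "overhang_pre": self.overhang_pre,
            "overhang_post": self.overhang_post,
        }


def curate(
    records: list[ScFvRecord],
    overhang_pre: str = "",
    overhang_post: str = "",
) -> Curation:
    """Three-step curation of labelled records.

    1. collapse exact (sequence, label) duplicates;
    2. drop every record whose sequence occurs with conflicting labels;
    3. prepend/append the configured overhang strings to each survivor.
    """
    seen: dict[tuple[str, int | None], ScFvRecord] = {}
    removed_dup = 0
    for rec in records:
        key = (rec.sequence, rec.label)
        if key in seen:
            removed_dup += 1
        else:
            seen[key] = rec
    labels_by_seq: dict[str, set[int | None]] = {}
    for seq, label in seen:
        labels_by_seq.setdefault(seq, set()).add(label)
    ambiguous_seqs = {s for s, ls in labels_by_seq.items() if len(ls) > 1}
    removed_amb = sum(
        1 for rec in records if rec.sequence in ambiguous_seqs
    )
    final = []
    for (seq, label), rec in seen.items():
        if seq in ambiguous_seqs:
            continue
        if overhang_pre or overhang_post:
            rec = ScFvRecord(
                id=rec.id,
                sequence=overhang_pre + seq + overhang_post,
                label=label,
                structure_path=rec.structure_path,
                structure=rec.structure,
            )
        final.append(rec)
    return Curation(
        input_count=len(records),
        removed_duplicates=removed_dup,
        removed_ambiguous=removed_amb,
        overhang_pre=overhang_pre,
        overhang_post=overhang_post,
        final_records=final,
    )


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratify: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def stratified_split(
    records: list[ScFvRecord], spec: SplitSpec = SplitSpec()
) -> tuple[list[ScFvRecord], list[ScFvRecord]]:
    """Deterministic stratified train/test partition.

    The test side receives ``ceil((1 - train_fraction) * N)`` records,
    allocated across classes proportionally (largest-remainder rule), so the
    class proportions of train and full set differ by at most one record per
    class.  For the reference screen's counts (8,867 / 10,559 at 80%) this
    yields the 15,540 / 3,886 partition.
    """
    labels = sorted({r.label for r in records}, key=lambda x: (x is None, x))
    by_class = {lab: [r for r in records if r.label == lab] for lab in labels}
    if spec.stratify:
        for lab, members in by_class.items():
            if len(members) < 2:
                raise SplitError(f"class {lab!r} has fewer than 2 records")
    n = len(records)
    test_total = math.ceil((1.0 - spec.train_fraction) * n)
    if not spec.stratify:
        by_class = {None: list(records)}
    raw = {
        lab: (1.0 - spec.train_fraction) * len(members)
        for lab, members in by_class.items()
    }
    base = {lab: math.floor(v) for lab, v in raw.items()}
    remainder = test_total - sum(base.values())
    order = sorted(raw, key=lambda lab: raw[lab] - base[lab], reverse=True)
    counts = dict(base)
    for lab in order[:remainder]:
        counts[lab] += 1
    rng = np.random.default_rng(spec.seed)
    train: list[ScFvRecord] = []
    test: list[ScFvRecord] = []
    for lab, members in by_class.items():
        idx = rng.permutation(len(members))
        k = counts[lab]
        test.extend(members[i] for i in idx[:k])
        train.extend(members[i] for i in idx[k:])
    return train, test


# ---------------------------------------------------------------------------
# Synthetic generator

# CDR residue frequencies: loop-biased composition (Gly/Ser/Tyr/Asp rich,
# moderate Trp/Arg) so that planted charge and Trp-content signals vary.
_CDR_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_CDR_WEIGHTS = np.array(
    [
        0.07,  # A
        0.01,  # C
        0.08,  # D
        0.03,  # E
        0.04,  # F
        0.14,  # G
        0.02,  # H
        0.03,  # I
        0.04,  # K
        0.04,  # L
        0.02,  # M
        0.04,  # N
        0.03,  # P
        0.03,  # Q
        0.06,  # R
        0.13,  # S
        0.06,  # T
        0.04,  # V
        0.05,  # W
        0.04,  # Y
    ]
)
_CDR_WEIGHTS = _CDR_WEIGHTS / _CDR_WEIGHTS.sum()

# CDR length ranges (inclusive); H3 is the hypervariable loop.
_CDR_LENGTH_RANGES = {
    "H1": (6, 8),
    "H2": (4, 6),
    "H3": (8, 16),
    "L1": (10, 12),
    "L2": (6, 8),
    "L3": (8, 10),
}

# Logistic label rule on planted loop properties.  Coefficients follow the
# direction of the known nonspecificity signals: more CDR-H3 tryptophan,
# more negative CDR2 charge, and longer CDR1 all raise the probability.
_SIGNAL_COEF = {"trp_ratio_h3": 9.0, "charge_cdr2": -0.55, "len_cdr1": 0.14}
_SIGNAL_STEEPNESS = 4.0


@dataclass(frozen=True)
class SignalSpec:
    coefficients: dict[str, float] = field(
        default_factory=lambda: dict(_SIGNAL_COEF)
    )
    steepness: float = _SIGNAL_STEEPNESS


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside one generated record."""

    heavy_span: tuple[int, int]  # indices of VH in the full sequence
    linker_span: tuple[int, int]
    light_span: tuple[int, int]
    cdr_spans_h: dict[str, tuple[int, int]]  # indices into the VH chain
    cdr_spans_l: dict[str, tuple[int, int]]  # indices into the VL chain
    cdr_seqs: dict[str, str]
    features: dict[str, float]  # planted feature values
    logit: float
    prob: float


def _sample_cdr(rng: np.random.Generator, name: str) -> str:
    lo, hi = _CDR_LENGTH_RANGES[name]
    length = int(rng.integers(lo, hi + 1))
    letters = rng.choice(len(_CDR_ALPHABET), size=length, p=_CDR_WEIGHTS)
    return "".join(_CDR_ALPHABET[i] for i in letters)


def _pseudo_structure(
    rng: np.random.Generator, sequence: str
) -> StructureModel:
    """Synthetic C-alpha coil model for one scFv.

    A 3.8-A-step random walk pulled toward its running centroid, giving a
    compact globule whose size and shape vary per record.  This is a
    synthetic stand-in for a predicted structure: it carries no sequence-
    dependent geometry beyond chain length.
    """
    n = len(sequence)
    coords = np.zeros((n, 3))
    pos = np.zeros(3)
    centroid = np.zeros(3)
    pull = 0.035
    for i in range(1, n):
        step = rng.normal(size=3)
        step /= np.linalg.norm(step)
        drift = centroid - pos
        norm = np.linalg.norm(drift)
        if norm > 0:
            step = step + pull * drift
            step /= np.linalg.norm(step)
        pos = pos + 3.8 * step
        coords[i] = pos
        centroid = coords[: i + 1].mean(axis=0)
    masses = np.array([RESIDUE_MASSES_1.get(aa, 110.0) for aa in sequence])
    return StructureModel(
        coords=coords,
        masses=masses,
        elements=["C"] * n,
        residues=list(sequence),
        chains=["A"] * n,
    )


def generate_synthetic(
    n: int,
    class_balance: float = DEFAULT_CLASS_BALANCE,
    seed: int = 0,
    signal_spec: SignalSpec | None = None,
    with_structures: bool = True,
    linker: str = DEFAULT_LINKER,
) -> tuple[list[ScFvRecord], list[SyntheticTruth]]:
    """Generate ``n`` labelled synthetic scFv records with ground truth.

    Labels are Bernoulli draws from ``sigmoid(steepness * (z - t))`` where
    ``z`` is the linear signal on planted loop properties and the threshold
    ``t`` is the (1 - class_balance) quantile of ``z`` over the batch, so
    the expected positive fraction matches ``class_balance``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    spec = signal_spec or SignalSpec()
    rng = np.random.default_rng(seed)
    charge_model = IntegerChargeModel()

    sequences: list[str] = []
    truths: list[SyntheticTruth] = []
    zs = np.empty(n)
    for i in range(n):
        cdrs = {name: _sample_cdr(rng, name) for name in _CDR_LENGTH_RANGES}
        fh = VH_TEMPLATE.frameworks
        fl = VL_TEMPLATE.frameworks
        vh_parts = [fh[0], cdrs["H1"], fh[1], cdrs["H2"], fh[2], cdrs["H3"], fh[3]]
        vl_parts = [fl[0], cdrs["L1"], fl[1], cdrs["L2"], fl[2], cdrs["L3"], fl[3]]
        vh = "".join(vh_parts)
        vl = "".join(vl_parts)
        seq = vh + linker + vl

        def spans(parts: list[str]) -> dict[str, tuple[int, int]]:
            out = {}
            off = 0
            for part, name in zip(parts, (None, 1, None, 2, None, 3, None)):
                if name is not None:
                    out[name] = (off, off + len(part))
                off += len(part)
            return out

        sh = spans(vh_parts)
        sl = spans(vl_parts)
        trp_ratio_h3 = cdrs["H3"].count("W") / len(cdrs["H3"])
        charge_cdr2 = cdr_net_charge(cdrs["H2"] + cdrs["L2"], charge_model)
        len_cdr1 = len(cdrs["H1"]) + len(cdrs["L1"])
        feats = {
            "trp_ratio_h3": trp_ratio_h3,
            "charge_cdr2": charge_cdr2,
            "len_cdr1": float(len_cdr1),
        }
        z = sum(spec.coefficients[k] * feats[k] for k in spec.coefficients)
        zs[i] = z
        sequences.append(seq)
        truths.append(
            SyntheticTruth(
                heavy_span=(0, len(vh)),
                linker_span=(len(vh), len(vh) + len(linker)),
                light_span=(len(vh) + len(linker), len(seq)),
                cdr_spans_h={f"H{k}": v for k, v in sh.items()},
                cdr_spans_l={f"L{k}": v for k, v in sl.items()},
                cdr_seqs=cdrs,
                features=feats,
                logit=z,
                prob=float("nan"),
            )
        )

    threshold = float(np.quantile(zs, 1.0 - class_balance))
    probs = 1.0 / (1.0 + np.exp(-spec.steepness * (zs - threshold)))
    labels = (rng.random(n) < probs).astype(int)

    records: list[ScFvRecord] = []
    for i, (seq, truth) in enumerate(zip(sequences, truths)):
        truth.logit = float(zs[i])
        truth.prob = float(probs[i])
        structure = _pseudo_structure(rng, seq) if with_structures else None
        records.append(
            ScFvRecord(
                id=f"syn{i:05d}",
                sequence=seq,
                label=int(labels[i]),
                structure=structure,
            )
        )
    return records, truths


# ---------------------------------------------------------------------------
# Tabular I/O


def records_to_frame(records: list[ScFvRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "sequence": [r.sequence for r in records],
            "label": [r.label for r in records],
        }
    )


def read_records_csv(path) -> list[ScFvRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        label = None if pd.isna(row.label) else int(row.label)
        records.append(
            ScFvRecord(id=str(row.id), sequence=row.sequence, label=label)
        )
    return records


def write_records_csv(records: list[ScFvRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
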