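"""scFv chain splitting, Chothia numbering, and CDR delimitation.

An scFv is a single polypeptide ``VH - (G4S)n linker - VL`` (or the reverse
orientation).  This module locates the linker, numbers each variable domain
with a Chothia-style scheme, and extracts the six CDR loops (H1-H3, L1-L3).

Numbering is template-anchored: each chain is parsed against a built-in human
consensus template (VH3-23-like heavy, IGKV1-39-like kappa light) whose
residues carry canonical Chothia positions.  Framework segments are treated
as fixed length -- insertions and deletions are confined to the CDR windows,
which is where they overwhelmingly occur in natural variable domains.  The
parse that maximises framework identity is selected by exhaustive search
over the three CDR lengths; a configurable identity fraction (default 0.40)
gates unalignable chains.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import AnnotationError

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

# (G4S)n, the standard scFv linker, at least two repeats.  A raw
# "Gly/Ser run >= 10" rule would swallow the C-terminal serines of the
# heavy framework (...VTVSS), so the repeat motif is the default; the
# pattern is configurable per construct.
DEFAULT_LINKER_PATTERN = r"(?:GGGGS){2,}"
DEFAULT_CHAIN_LENGTH_BOUNDS = (90, 150)
DEFAULT_IDENTITY_THRESHOLD = 0.40


@dataclass(frozen=True)
class ScFvRecord:
    """One scFv sequence with an optional binary polyreactivity label.

    ``label`` is 1 for polyreactive, 0 for non-polyreactive, ``None`` when
    unlabelled.  ``structure_path`` optionally points at a PDB file used for
    the structure-derived descriptors; ``structure`` may hold an in-memory
    model instead (the synthetic generator uses this).
    """

    id: str
    sequence: str
    label: int | None = None
    structure_path: str | None = None
    structure: object | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-canonical residues {sorted(bad)}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0/1 or None")


@dataclass(frozen=True)
class ChothiaLabel:
    """A Chothia position: integer number plus optional insertion letter."""

    number: int
    insertion: str = ""

    def __str__(self) -> str:
        return f"{self.number}{self.insertion}"

    def sort_key(self) -> tuple[int, str]:
        return (self.number, self.insertion)


@dataclass(frozen=True)
class CdrWindow:
    """Inclusive Chothia coordinates of one CDR plus its insertion anchor."""

    name: str
    start: int
    end: int
    anchor: int

    @property
    def slots(self) -> int:
        return self.end - self.start + 1


# Standard Chothia CDR windows.  Insertion anchors follow the usual
# convention of lettered positions (e.g. H3 insertions at 100A, 100B, ...).
CHOTHIA_CDRS: dict[str, tuple[CdrWindow, ...]] = {
    "H": (
        CdrWindow("H1", 26, 32, 31),
        CdrWindow("H2", 52, 56, 52),
        CdrWindow("H3", 95, 102, 100),
    ),
    "L": (
        CdrWindow("L1", 24, 34, 30),
        CdrWindow("L2", 50, 56, 54),
        CdrWindow("L3", 89, 97, 95),
    ),
}


@dataclass(frozen=True)
class ChainTemplate:
    """Consensus variable-domain template with fixed-length frameworks."""

    chain_type: str
    frameworks: tuple[str, str, str, str]
    cdrs: tuple[str, str, str]
    windows: tuple[CdrWindow, ...]

    def __post_init__(self) -> None:
        # template CDRs must exactly fill their Chothia windows so that the
        # full template is numbered 1..len with no insertions
        for cdr, win in zip(self.cdrs, self.windows):
            if len(cdr) != win.slots:
                raise ValueError(f"template {win.name}: length != window size")

    @property
    def sequence(self) -> str:
        f1, f2, f3, f4 = self.frameworks
        c1, c2, c3 = self.cdrs
        return f1 + c1 + f2 + c2 + f3 + c3 + f4

    @property
    def framework_length(self) -> int:
        return sum(len(f) for f in self.frameworks)


# Human consensus scaffolds: VH3-23-like heavy, IGKV1-39-like kappa light.
VH_TEMPLATE = ChainTemplate(
    chain_type="H",
    frameworks=(
        "EVQLLESGGGLVQPGGSLRLSCAAS",                # 1-25
        "AMSWVRQAPGKGLEWVSAI",                      # 33-51
        "ADSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAR",   # 57-94
        "WGQGTLVTVSS",                              # 103-113
    ),
    cdrs=("GFTFSSY", "SGSGG", "DRGYSSGW"),
    windows=CHOTHIA_CDRS["H"],
)

VL_TEMPLATE = ChainTemplate(
    chain_type="L",
    frameworks=(
        "DIQMTQSPSSLSASVGDRVTITC",              # 1-23
        "WYQQKPGKAPKLLIY",                      # 35-49
        "GVPSRFSGSGSGTDFTLTISSLQPEDFATYYC",     # 57-88
        "FGQGTKVEIK",                           # 98-107
    ),
    cdrs=("RASQSISSYLN", "AASSLQS", "QQSYSTPLT"),
    windows=CHOTHIA_CDRS["L"],
)

TEMPLATES: dict[str, ChainTemplate] = {"H": VH_TEMPLATE, "L": VL_TEMPLATE}


@dataclass
class AntibodyAnnotation:
    """Per-chain Chothia numbering and the six CDR spans of one scFv.

    ``cdr_spans`` maps CDR name to a half-open ``(start, end)`` index
    interval into the corresponding chain sequence (0-based).
    """

    heavy_seq: str
    light_seq: str
    numbering: dict[str, tuple[ChothiaLabel, ...]]
    cdr_spans: dict[str, tuple[int, int]]

    _CDR_ORDER = ("H1", "H2", "H3", "L1", "L2", "L3")

    def chain_of(self, cdr_name: str) -> str:
        return self.heavy_seq if cdr_name.startswith("H") else self.light_seq

    def cdr_seq(self, cdr_name: str) -> str:
        start, end = self.cdr_spans[cdr_name]
        return self.chain_of(cdr_name)[start:end]

    @property
    def cdr_concat(self) -> str:
        return "".join(self.cdr_seq(n) for n in self._CDR_ORDER)

    @property
    def cdr3_concat(self) -> str:
        return self.cdr_seq("H3") + self.cdr_seq("L3")

    @property
    def cdrh3(self) -> str:
        return self.cdr_seq("H3")


def split_scfv_chains(
    record: ScFvRecord,
    linker_pattern: str = DEFAULT_LINKER_PATTERN,
    orientation: str = "VH-VL",
) -> tuple[str, str]:
    """Split an scFv into (heavy, light) sequences at the flexible linker.

    The linker is located as the unique maximal match of ``linker_pattern``
    (default: a Gly/Ser run of length >= 10).  ``orientation`` states which
    domain precedes the linker.
    """
    matches = list(re.finditer(linker_pattern, record.sequence))
    if not matches:
        raise AnnotationError(f"record {record.id!r}: no linker")
    if len(matches) > 1:
        spans = [m.span() for m in matches]
        raise AnnotationError(
            f"record {record.id!r}: ambiguous linker, candidates at {spans}"
        )
    m = matches[0]
    before, after = record.sequence[: m.start()], record.sequence[m.end():]
    if not before or not after:
        raise AnnotationError(
            f"record {record.id!r}: linker at sequence boundary"
        )
    if orientation == "VH-VL":
        return before, after
    if orientation == "VL-VH":
        return after, before
    raise ValueError(f"unknown orientation {orientation!r}")


def _segment_matches(seq: str, off: int, segment: str) -> int:
    sub = seq[off: off + len(segment)]
    return sum(a == b for a, b in zip(sub, segment))


def _best_cdr_lengths(
    seq: str, template: ChainTemplate
) -> tuple[tuple[int, int, int], int]:
    """Exhaustive search for the CDR-length triple maximising framework
    identity.  Returns ((l1, l2, l3), matched framework residues).

    Framework segments are fixed length, so the parse has two degrees of
    freedom; per-segment match counts depend only on one offset each, which
    keeps the search O(S * L) for slack S.
    """
    f1, f2, f3, f4 = template.frameworks
    slack = len(seq) - template.framework_length
    if slack < 0:
        raise AnnotationError(
            f"chain shorter than template frameworks ({len(seq)} residues)"
        )
    m1 = _segment_matches(seq, 0, f1)
    m4 = _segment_matches(seq, len(seq) - len(f4), f4)
    base2 = len(f1)
    base3 = len(f1) + len(f2)
    # m2[l1]: matches of framework 2 when CDR1 has length l1
    m2 = [_segment_matches(seq, base2 + l1, f2) for l1 in range(slack + 1)]
    # m3[t]: matches of framework 3 when l1 + l2 == t
    m3 = [_segment_matches(seq, base3 + t, f3) for t in range(slack + 1)]

    canonical = tuple(w.slots for w in template.windows)
    best: tuple[int, int, int] | None = None
    best_score: tuple[int, int, int, int] | None = None
    for l1 in range(slack + 1):
        for l2 in range(slack - l1 + 1):
            l3 = slack - l1 - l2
            matches = m1 + m2[l1] + m3[l1 + l2] + m4
            dev = (
                abs(l1 - canonical[0])
                + abs(l2 - canonical[1])
                + abs(l3 - canonical[2])
            )
            score = (matches, -dev, -l1, -l2)
            if best_score is None or score > best_score:
                best_score = score
                best = (l1, l2, l3)
    assert best is not None and best_score is not None
    return best, best_score[0]


def _number_cdr(window: CdrWindow, length: int) -> list[ChothiaLabel]:
    """Number a CDR of ``length`` residues into its Chothia window.

    Deletions: fill positions left of the anchor first, then from the window
    end backwards.  Insertions: lettered positions at the anchor.
    """
    nl = window.anchor - window.start + 1
    nr = window.end - window.anchor
    if length <= nl + nr:
        kl = min(length, nl)
        kr = length - kl
        nums = list(range(window.start, window.start + kl))
        nums += list(range(window.end - kr + 1, window.end + 1))
        return [ChothiaLabel(n) for n in nums]
    n_ins = length - (nl + nr)
    if n_ins > 26:
        raise AnnotationError(f"{window.name}: more than 26 insertions")
    labels = [ChothiaLabel(n) for n in range(window.start, window.anchor + 1)]
    labels += [
        ChothiaLabel(window.anchor, chr(ord("A") + i)) for i in range(n_ins)
    ]
    labels += [
        ChothiaLabel(n) for n in range(window.anchor + 1, window.end + 1)
    ]
    return labels


def number_chothia(
    chain_seq: str,
    chain_type: str,
    *,
    length_bounds: tuple[int, int] = DEFAULT_CHAIN_LENGTH_BOUNDS,
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> tuple[ChothiaLabel, ...]:
    """Assign a Chothia position label to every residue of a chain."""
    if chain_type not in TEMPLATES:
        raise ValueError(f"chain_type must be H or L, got {chain_type!r}")
    lo, hi = length_bounds
    if not lo <= len(chain_seq) <= hi:
        raise AnnotationError(
            f"{chain_type} chain length {len(chain_seq)} outside [{lo}, {hi}]"
        )
    template = TEMPLATES[chain_type]
    (l1, l2, l3), matched = _best_cdr_lengths(chain_seq, template)
    identity = matched / template.framework_length
    if identity < identity_threshold:
        raise AnnotationError(
            f"{chain_type} chain framework identity {identity:.2f} below "
            f"threshold {identity_threshold:.2f}"
        )
    labels: list[ChothiaLabel] = []
    pos = 1
    for fr, win, cdr_len in zip(
        template.frameworks[:3], template.windows, (l1, l2, l3)
    ):
        labels += [ChothiaLabel(pos + i) for i in range(len(fr))]
        pos += len(fr)
        labels += _number_cdr(win, cdr_len)
        pos = win.end + 1
    f4 = template.frameworks[3]
    labels += [ChothiaLabel(pos + i) for i in range(len(f4))]
    assert len(labels) == len(chain_seq)
    return tuple(labels)


def delimit_cdrs(
    numbering: Sequence[ChothiaLabel], chain_type: str
) -> dict[str, tuple[int, int]]:
    """Half-open index spans of the CDRs, read off the numbering.

    A residue belongs to a CDR when its Chothia number lies inside the
    configured window (insertion-lettered positions included).
    """
    spans: dict[str, tuple[int, int]] = {}
    for win in CHOTHIA_CDRS[chain_type]:
        idx = [
            i
            for i, lab in enumerate(numbering)
            if win.start <= lab.number <= win.end
        ]
        if not idx:
            raise AnnotationError(f"{win.name}: no residues in window")
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise AnnotationError(f"{win.name}: non-contiguous span")
        spans[win.name] = (idx[0], idx[-1] + 1)
    return spans


def annotate_scfv(
    record: ScFvRecord,
    *,
    linker_pattern: str = DEFAULT_LINKER_PATTERN,
    orientation: str = "VH-VL",
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
    length_bounds: tuple[int, int] = DEFAULT_CHAIN_LENGTH_BOUNDS,
) -> AntibodyAnnotation:
    """Full annotation: split chains, number both, delimit all six CDRs."""
    heavy, light = split_scfv_chains(record, linker_pattern, orientation)
    numbering = {
        "H": number_chothia(
            heavy,
            "H",
            length_bounds=length_bounds,
            identity_threshold=identity_threshold,
        ),
        "L": number_chothia(
            light,
            "L",
            length_bounds=length_bounds,
            identity_threshold=identity_threshold,
        ),
    }
    spans = delimit_cdrs(numbering["H"], "H")
    spans.update(delimit_cdrs(numbering["L"], "L"))
    return AntibodyAnnotation(
        heavy_seq=heavy,
        light_seq=light,
        numbering=numbering,
        cdr_spans=spans,
    )


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> list[ScFvRecord]:
    """Read scFv records from FASTA; a ``label=<0|1>`` token in the
    description becomes the polyreactivity label."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        label = None
        m = re.search(r"label=([01])", rec.description)
        if m:
            label = int(m.group(1))
        records.append(ScFvRecord(id=rec.id, sequence=str(rec.seq), label=label))
    return records


def write_fasta(records: Iterable[ScFvRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            label = "" if rec.label is None else f" label={rec.label}"
            fh.write(f">{rec.id}{label}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i: i + 60] + "\n")


def _annotation_rows(
    record_id: str, ann: AntibodyAnnotation
) -> Iterator[dict[str, object]]:
    for name in AntibodyAnnotation._CDR_ORDER:
        start, end = ann.cdr_spans[name]
        yield {
            "id": record_id,
            "chain": name[0],
            "cdr": name,
            "start": start,
            "end": end,
            "sequence": ann.cdr_seq(name),
        }


def write_annotations_csv(
    annotations: dict[str, AntibodyAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["id", "chain", "cdr", "start", "end", "sequence"]
        )
        writer.writeheader()
        for rid, ann in annotations.items():
            for row in _annotation_rows(rid, ann):
                writer.writerow(row)


def write_annotations_json(
    annotations: dict[str, AntibodyAnnotation], path: str | Path
) -> None:
    payload = {
        rid: {
            "heavy_seq": ann.heavy_seq,
            "light_seq": ann.light_seq,
            "numbering": {
                c: [str(lab) for lab in labs]
                for c, labs in ann.numbering.items()
            },
            "cdr_spans": {k: list(v) for k, v in ann.cdr_spans.items()},
            "cdrs": {
                n: ann.cdr_seq(n) for n in AntibodyAnnotation._CDR_ORDER
            },
        }
        for rid, ann in annotations.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
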