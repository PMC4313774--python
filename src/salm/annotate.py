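"""Precursor annotation: signal peptide, cleavage sites, mature peptides.

A neuropeptide precursor (prepropeptide) is an N-terminal signal peptide
followed by peptide copies separated by basic prohormone-convertase
cleavage sites. A C-terminal glycine on a liberated peptide is the
amidation donor: carboxypeptidase trimming and PAM oxidation convert it
into an amide on the preceding residue, so an extracted candidate ending
in G is stored with the G removed and ``amidated=True``.

The annotation procedure is:

1. signal peptide by a hydrophobic-core + (−3,−1) small-residue
   heuristic (von Heijne-style), overridable per record so published
   annotations can be pinned;
2. dibasic sites (KR, RR, KK, RK) downstream of the signal, parsed
   greedily left-to-right so overlapping basic runs resolve
   deterministically;
3. two-pass peptide extraction: inter-site segments first (dibasic-only
   pass), then a monobasic rescue pass in which single K/R cuts are
   honored only where they release an amidated peptide that classifies
   into one of the four SALMFamide categories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import motif as motif_mod
from .motif import Category, MotifCategory, PrecursorTypeCall, call_precursor_type
from .seqio import SequenceRecord

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5, "E": -3.5,
    "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8,
    "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2, "X": 0.0,
}

DIBASIC_KINDS = {"KR": "KR", "RR": "RR", "KK": "KK", "RK": "RK"}
SMALL_MINUS1 = frozenset("AGSCT")
SMALL_MINUS3 = frozenset("AGSCTVIL")

HYDROPHOBIC_WINDOW = 8
HYDROPHOBIC_MIN_MEAN = 1.6
CLEAVE_MIN, CLEAVE_MAX = 15, 45
DISTANCE_PENALTY = 0.05
PREFERRED_SIGNAL_END = 25


@dataclass(frozen=True)
class SignalPeptide:
    """Predicted signal peptide; ``span`` always starts at residue 0."""

    span: tuple[int, int]
    score: float

    def __post_init__(self) -> None:
        start, end = self.span
        if start != 0:
            raise ValueError("signal peptide must start at residue 0")
        if not 10 <= end <= 45:
            raise ValueError(f"signal peptide end {end} outside [10, 45]")

    @property
    def end(self) -> int:
        return self.span[1]


@dataclass(frozen=True)
class CleavageSite:
    """A mono- or dibasic convertase site; ``pos`` indexes its first residue."""

    pos: int
    kind: str  # KR, RR, KK, RK, mono_K, mono_R

    @property
    def width(self) -> int:
        return 1 if self.kind.startswith("mono") else 2

    @property
    def end(self) -> int:
        return self.pos + self.width


@dataclass(frozen=True)
class MaturePeptide:
    """A peptide released from a precursor.

    ``sequence`` excludes the glycine amidation donor when ``amidated``;
    ``span`` is the interval of the stored sequence in the precursor and
    ``ordinal`` is the peptide's 1-based N→C rank.
    """

    sequence: str
    amidated: bool
    span: tuple[int, int]
    ordinal: int = 0
    category: MotifCategory | None = None

    def __post_init__(self) -> None:
        if self.span[1] - self.span[0] != len(self.sequence):
            raise ValueError("span does not match stored sequence length")


@dataclass
class PrecursorAnnotation:
    record: SequenceRecord
    signal: SignalPeptide | None
    sites: list[CleavageSite]
    peptides: list[MaturePeptide]
    composition: dict[Category, int] = field(default_factory=dict)

    @property
    def type_call(self) -> PrecursorTypeCall:
        return call_precursor_type(self.composition)


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable parameters of the annotation procedure."""

    min_len: int = 5
    require_amidation: bool = True
    min_protein_len: int = 30
    # per-record signal cleavage override: record id -> signal end
    signal_overrides: Mapping[str, int] = field(default_factory=dict)


def predict_signal_peptide(protein: str) -> SignalPeptide | None:
    """Heuristic signal-peptide call.

    Requires a hydrophobic core — an 8-residue window within residues
    1–30 whose mean Kyte–Doolittle hydropathy is ≥ 1.6 — and then scores
    candidate cleavage positions 15–45 by the (−3,−1) small-residue rule
    (+1 when the residue at −1 is one of A/G/S/C/T, +1 when the residue
    at −3 is small or an aliphatic V/I/L) minus 0.05 per residue of
    distance from position 25. Smallest end wins ties. Returns None when
    no hydrophobic core exists.
    """
    if len(protein) < 30:
        raise ValueError("protein shorter than 30 residues")
    core = False
    # window must lie wholly within the first 30 residues
    for start in range(0, min(30 - HYDROPHOBIC_WINDOW, len(protein) - HYDROPHOBIC_WINDOW) + 1):
        window = protein[start : start + HYDROPHOBIC_WINDOW]
        if sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in window) / HYDROPHOBIC_WINDOW >= (
            HYDROPHOBIC_MIN_MEAN
        ):
            core = True
            break
    if not core:
        return None
    best: tuple[float, int] | None = None
    for end in range(CLEAVE_MIN, min(CLEAVE_MAX, len(protein) - 1) + 1):
        bonus = (protein[end - 1] in SMALL_MINUS1) + (protein[end - 3] in SMALL_MINUS3)
        score = bonus - DISTANCE_PENALTY * abs(end - PREFERRED_SIGNAL_END)
        if best is None or score > best[0]:
            best = (score, end)
    assert best is not None
    return SignalPeptide(span=(0, best[1]), score=best[0])


def find_cleavage_sites(
    protein: str, signal_end: int, monobasic_positions: Iterable[int] = ()
) -> list[CleavageSite]:
    """Basic cleavage sites downstream of the signal peptide.

    All dibasic pairs (KR, RR, KK, RK) are reported; overlapping basic
    runs (e.g. KRR) are resolved greedily left-to-right into
    non-overlapping sites. Monobasic K/R positions are included only when
    explicitly flagged eligible (the amidation+classifiability gate of
    :func:`extract_peptides`).
    """
    if signal_end >= len(protein):
        raise ValueError("signal_end beyond protein length")
    mono = set(monobasic_positions)
    sites: list[CleavageSite] = []
    i = signal_end
    while i < len(protein) - 1:
        pair = protein[i : i + 2]
        if pair in DIBASIC_KINDS:
            sites.append(CleavageSite(pos=i, kind=pair))
            i += 2
            continue
        if i in mono and protein[i] in "KR":
            sites.append(CleavageSite(pos=i, kind=f"mono_{protein[i]}"))
        i += 1
    if len(protein) - 1 in mono and protein[-1] in "KR":
        sites.append(CleavageSite(pos=len(protein) - 1, kind=f"mono_{protein[-1]}"))
    return sites


def _strip_stray_basics(seq: str, start: int) -> tuple[str, int]:
    """Strip leading/trailing stray K/R; returns (stripped, new_start)."""
    while seq and seq[0] in "KR":
        seq, start = seq[1:], start + 1
    while seq and seq[-1] in "KR":
        seq = seq[:-1]
    return seq, start


def _candidate(seq: str, start: int, min_len: int) -> MaturePeptide | None:
    """Turn a raw inter-site segment into a mature-peptide candidate."""
    seq, start = _strip_stray_basics(seq, start)
    if not seq:
        return None
    if seq.endswith("G"):
        stored = seq[:-1]
        amidated = True
    else:
        stored = seq
        amidated = False
    if len(stored) < min_len:
        return None
    return MaturePeptide(sequence=stored, amidated=amidated, span=(start, start + len(stored)))


def _segments(
    protein: str, start: int, sites: Sequence[CleavageSite]
) -> list[tuple[int, int]]:
    bounds = [start]
    for s in sites:
        bounds.extend((s.pos, s.end))
    bounds.append(len(protein))
    return [(bounds[i], bounds[i + 1]) for i in range(0, len(bounds), 2)]


def extract_peptides(
    protein: str,
    signal: SignalPeptide | None,
    sites: Sequence[CleavageSite],
    min_len: int = 5,
    require_amidation: bool = True,
) -> tuple[list[MaturePeptide], list[CleavageSite]]:
    """Two-pass peptide extraction.

    Pass 1 cuts at the supplied (dibasic) sites only: every inter-site
    segment — including the stretch between signal end and first site
    and after the last site — becomes a candidate; stray boundary K/R
    residues are stripped, a terminal G marks amidation, and
    non-amidated candidates are dropped when ``require_amidation``.

    Pass 2 (monobasic rescue) re-scans segments that yielded no peptide:
    scanning left to right, a single K/R is accepted as a cleavage site
    exactly when the peptide it would release is amidated and classifies
    into one of the four SALMFamide categories. Rescue only ever adds
    peptides (monotone augmentation).

    Returns the peptides (ordinals assigned N→C) and the full site list
    including accepted monobasic sites, sorted by position.
    """
    start = signal.end if signal is not None else 0
    dibasic = sorted((s for s in sites if s.width == 2), key=lambda s: s.pos)
    peptides: list[MaturePeptide] = []
    mono_sites: list[CleavageSite] = []

    for seg_start, seg_end in _segments(protein, start, dibasic):
        if seg_start >= seg_end:
            continue
        cand = _candidate(protein[seg_start:seg_end], seg_start, min_len)
        if cand is not None and (cand.amidated or not require_amidation):
            peptides.append(cand)
            continue
        # monobasic rescue within this segment
        cursor = seg_start
        for pos in range(seg_start, seg_end):
            if protein[pos] not in "KR" or pos < cursor:
                continue
            sub = _candidate(protein[cursor:pos], cursor, min_len)
            if (
                sub is not None
                and sub.amidated
                and len(sub.sequence) >= 3
                and motif_mod.classify_peptide(sub).category is not Category.ATYPICAL
            ):
                peptides.append(sub)
                mono_sites.append(CleavageSite(pos=pos, kind=f"mono_{protein[pos]}"))
                cursor = pos + 1
        if cursor > seg_start:
            tail = _candidate(protein[cursor:seg_end], cursor, min_len)
            if tail is not None and (tail.amidated or not require_amidation):
                peptides.append(tail)

    peptides.sort(key=lambda p: p.span)
    peptides = [
        MaturePeptide(
            sequence=p.sequence,
            amidated=p.amidated,
            span=p.span,
            ordinal=i + 1,
            category=motif_mod.classify_sequence(p.sequence, p.amidated)
            if len(p.sequence) >= 3
            else MotifCategory(Category.ATYPICAL, canonical=False),
        )
        for i, p in enumerate(peptides)
    ]
    all_sites = sorted(list(dibasic) + mono_sites, key=lambda s: s.pos)
    return peptides, all_sites


def annotate_precursor(
    record: SequenceRecord, config: AnnotationConfig | None = None
) -> PrecursorAnnotation:
    """Full annotation of one precursor protein record."""
    config = config or AnnotationConfig()
    if record.alphabet_kind != "protein":
        raise ValueError(f"record {record.id} is not a protein")
    protein = record.seq
    if record.id in config.signal_overrides:
        end = config.signal_overrides[record.id]
        signal = SignalPeptide(span=(0, end), score=float("nan"))
    elif len(protein) >= config.min_protein_len:
        signal = predict_signal_peptide(protein)
    else:
        signal = None
    sites = find_cleavage_sites(protein, signal.end if signal else 0)
    peptides, all_sites = extract_peptides(
        protein,
        signal,
        sites,
        min_len=config.min_len,
        require_amidation=config.require_amidation,
    )
    composition = {cat: 0 for cat in motif_mod.CATEGORY_ORDER}
    for p in peptides:
        composition[p.category.category] += 1
    return PrecursorAnnotation(
        record=record,
        signal=signal,
        sites=all_sites,
        peptides=peptides,
        composition=composition,
    )


def annotation_to_dict(ann: PrecursorAnnotation) -> dict:
    """JSON-serializable view of an annotation (1-based inclusive spans)."""
    return {
        "id": ann.record.id,
        "length": len(ann.record.seq),
        "signal": None
        if ann.signal is None
        else {"span": [1, ann.signal.end], "score": ann.signal.score},
        "sites": [{"pos": s.pos + 1, "kind": s.kind} for s in ann.sites],
        "peptides": [
            {
                "ordinal": p.ordinal,
                "sequence": p.sequence,
                "amidated": p.amidated,
                "span": [p.span[0] + 1, p.span[1]],
                "category": str(p.category.category) if p.category else None,
                "canonical": bool(p.category.canonical) if p.category else None,
            }
            for p in ann.peptides
        ],
        "composition": {str(cat): n for cat, n in ann.composition.items()},
        "type_call": ann.type_call.call.value,
    }


def annotations_to_json(annotations: Iterable[PrecursorAnnotation]) -> str:
    return json.dumps([annotation_to_dict(a) for a in annotations], indent=2)


def peptides_to_bed(annotations: Iterable[PrecursorAnnotation]) -> str:
    """BED-like TSV of peptide intervals on their precursors (0-based)."""
    lines = []
    for ann in annotations:
        for p in ann.peptides:
            cat = str(p.category.category) if p.category else "."
            lines.append(
                "\t".join(
                    [
                        ann.record.id,
                        str(p.span[0]),
                        str(p.span[1]),
                        f"{p.sequence}{'amide' if p.amidated else ''}",
                        cat,
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")
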