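"""C-terminal motif classification of SALMFamide-type neuropeptides.

SALMFamides are C-terminally amidated echinoderm neuropeptides whose
family membership is read off the last and antepenultimate residues of
the amidated peptide. Writing ``a`` for the residue at −1 and ``b`` for
the residue at −3, the four-way scheme is:

===========  ==============  ==============  =================
category     a (−1)          b (−3)          serialized name
===========  ==============  ==============  =================
L_TYPE       F               L, I or M       LxF
F_TYPE       F               F or Y          FxF
FXL_TYPE     L or M          F or Y          FxL
LXL_TYPE     L or M          L, I or M       LxL
===========  ==============  ==============  =================

Leucine-like substitutes are {L, I, M} and phenylalanine-like are
{F, Y}; a peptide is *canonical* when the strict letter matches (e.g.
L at −3 for LxF). Anything else — including any non-amidated peptide —
is ATYPICAL. Precursors are typed by which category dominates their
peptide complement.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import MaturePeptide, PrecursorAnnotation

LEUCINE_LIKE = frozenset("LIM")
PHENYLALANINE_LIKE = frozenset("FY")


class Category(enum.Enum):
    """Four-way C-terminal motif category plus a catch-all."""

    L_TYPE = "LxF"
    F_TYPE = "FxF"
    FXL_TYPE = "FxL"
    LXL_TYPE = "LxL"
    ATYPICAL = "atypical"

    def __str__(self) -> str:  # serialized exactly as LxF/FxF/FxL/LxL/atypical
        return self.value


CATEGORY_ORDER = (
    Category.L_TYPE,
    Category.F_TYPE,
    Category.FXL_TYPE,
    Category.LXL_TYPE,
    Category.ATYPICAL,
)


@dataclass(frozen=True)
class MotifCategory:
    category: Category
    canonical: bool


@dataclass(frozen=True)
class Motif:
    """A C-terminal consensus pattern, ``x`` marking variable positions."""

    pattern: str
    amidated: bool = True

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("empty motif pattern")
        if self.pattern[-1] == "x":
            raise ValueError("motif must end in a residue, not a wildcard")

    def rendered(self) -> str:
        return self.pattern + ("amide" if self.amidated else "")


class PrecursorType(enum.Enum):
    L_PRECURSOR = "L_PRECURSOR"
    F_PRECURSOR = "F_PRECURSOR"
    MIXED = "MIXED"
    UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class PrecursorTypeCall:
    call: PrecursorType
    support: Mapping[Category, int]


def classify_sequence(sequence: str, amidated: bool) -> MotifCategory:
    """Classify a mature peptide sequence by its C-terminal motif.

    ``sequence`` is the mature peptide *without* the glycine amidation
    donor. The category is a pure function of ``amidated`` and the
    residues at −1 and −3; unknown residues (X) match nothing.
    """
    if len(sequence) < 3:
        raise ValueError(f"peptide too short to classify: {sequence!r}")
    if not amidated:
        return MotifCategory(Category.ATYPICAL, canonical=False)
    a, b = sequence[-1], sequence[-3]
    if a == "F" and b in LEUCINE_LIKE:
        return MotifCategory(Category.L_TYPE, canonical=b == "L")
    if a == "F" and b in PHENYLALANINE_LIKE:
        return MotifCategory(Category.F_TYPE, canonical=b == "F")
    if a in "LM" and b in PHENYLALANINE_LIKE:
        return MotifCategory(Category.FXL_TYPE, canonical=(a == "L" and b == "F"))
    if a in "LM" and b in LEUCINE_LIKE:
        return MotifCategory(Category.LXL_TYPE, canonical=(a == "L" and b == "L"))
    return MotifCategory(Category.ATYPICAL, canonical=False)


def classify_peptide(peptide: "MaturePeptide") -> MotifCategory:
    """Classify a :class:`~salm.annotate.MaturePeptide`."""
    return classify_sequence(peptide.sequence, peptide.amidated)


def consensus_motif(sequences: Iterable[str], amidated: bool = True) -> Motif:
    """Derive the shared C-terminal motif of a set of amidated peptides.

    Peptides are aligned at their C-termini; each position from −1
    leftward emits the shared residue, or ``x`` where they differ. The
    scan stops before the first position at which any peptide is
    exhausted, and leading wildcards are stripped.
    """
    seqs = [s for s in sequences]
    if not seqs:
        raise ValueError("consensus_motif requires at least one peptide")
    depth = min(len(s) for s in seqs)
    out: list[str] = []
    for i in range(1, depth + 1):
        column = {s[-i] for s in seqs}
        out.append(column.pop() if len(column) == 1 else "x")
    pattern = "".join(reversed(out)).lstrip("x")
    return Motif(pattern=pattern, amidated=amidated)


def composition_of(peptides: Iterable["MaturePeptide"]) -> dict[Category, int]:
    """Count peptides per category (all five keys always present)."""
    counts = Counter(classify_peptide(p).category for p in peptides)
    return {cat: counts.get(cat, 0) for cat in CATEGORY_ORDER}


def call_precursor_type(
    annotation_or_composition: "PrecursorAnnotation | Mapping[Category, int]",
) -> PrecursorTypeCall:
    """Type a precursor from its peptide composition.

    Among non-ATYPICAL peptides: L_PRECURSOR when the LxF count is
    strictly greatest and at least half of the classified peptides;
    F_PRECURSOR symmetrically; UNDETERMINED with fewer than two
    classified peptides; otherwise MIXED. Invariant to peptide order and
    to the ATYPICAL count.
    """
    comp = getattr(annotation_or_composition, "composition", annotation_or_composition)
    counts = {cat: int(comp.get(cat, 0)) for cat in CATEGORY_ORDER}
    classified = sum(v for cat, v in counts.items() if cat is not Category.ATYPICAL)
    if classified < 2:
        return PrecursorTypeCall(PrecursorType.UNDETERMINED, counts)
    for cat, call in (
        (Category.L_TYPE, PrecursorType.L_PRECURSOR),
        (Category.F_TYPE, PrecursorType.F_PRECURSOR),
    ):
        n = counts[cat]
        others = [
            counts[c] for c in CATEGORY_ORDER if c not in (cat, Category.ATYPICAL)
        ]
        if n > max(others) and 2 * n >= classified:
            return PrecursorTypeCall(call, counts)
    return PrecursorTypeCall(PrecursorType.MIXED, counts)
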