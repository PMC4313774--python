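"""Synthetic precursor/transcriptome generator with planted ground truth.

Emulates the architecture the annotation pipeline assumes: an N-terminal
signal peptide (hydrophobic core, A-x-A cleavage), then amidated
peptides ending in a glycine donor bounded by mono/dibasic convertase
sites, interleaved with acidic spacer regions, embedded in a transcript
with untranslated regions among decoy transcripts. Every stochastic
choice flows through one seeded numpy Generator (PCG64), so identical
seeds give bit-identical output.

Two deliberate simplifications keep planted truth exactly recoverable
(see the methods note): spacers use a non-basic, non-glycine alphabet
and every non-empty spacer is terminated by a dibasic site; boundaries
after planted ATYPICAL peptides are always dibasic, because monobasic
cleavage is only honored downstream when it releases a classifiable
peptide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .motif import CATEGORY_ORDER, Category
from .seqio import SequenceRecord

SIGNAL_CORE_ALPHABET = "LIVF"  # strongly hydrophobic, none (−3,−1)-small
SPACER_ALPHABET = "DENQPH"  # non-basic, non-G, not signal-cleavage-small
PEPTIDE_INTERIOR_ALPHABET = "ADEFGHILMNPQSTVWY"  # no K/R, no C
LEU_LIKE = "LIM"
PHE_LIKE = "FY"
ATYPICAL_TERMINAL = "QYTSHN"  # never F/L/M at −1 → classifies ATYPICAL
DIBASIC = ("KR", "RR", "KK", "RK")
STOPS = ("TAA", "TAG", "TGA")

_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_BY_AA:
    _CODONS_BY_AA[aa].sort()


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic study conditions."""

    n_precursors: int = 1
    peptides_per_precursor: tuple[int, int] = (3, 8)
    # probability over (LxF, FxF, FxL, LxL, atypical)
    category_mix: tuple[float, ...] = (0.4, 0.4, 0.1, 0.1, 0.0)
    signal_len: tuple[int, int] = (18, 25)
    dibasic_fraction: float = 0.8
    utr_len: tuple[int, int] = (30, 150)
    n_decoys: int = 50
    substitution_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_mix) - 1.0) > 1e-9 or len(self.category_mix) != 5:
            raise ValueError("category_mix must be 5 probabilities summing to 1")
        for name in ("peptides_per_precursor", "signal_len", "utr_len"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ValueError(f"empty range for {name}")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")
        if not 0.0 <= self.dibasic_fraction <= 1.0:
            raise ValueError("dibasic_fraction must be a probability")
        if self.signal_len[0] < 12 or self.signal_len[1] > 25:
            raise ValueError("signal_len must lie within [12, 25]")


@dataclass(frozen=True)
class PlantedPeptide:
    sequence: str  # without the G amidation donor
    span: tuple[int, int]  # of the stored sequence, in the precursor
    category: Category
    amidated: bool = True


@dataclass(frozen=True)
class TruthRecord:
    transcript_id: str
    protein: str
    signal_span: tuple[int, int]
    peptides: tuple[PlantedPeptide, ...]
    boundary_kinds: tuple[str, ...]


def _choice(rng: np.random.Generator, pool: str | Sequence[str]) -> str:
    return pool[int(rng.integers(len(pool)))]


def _randint(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _peptide_for_category(rng: np.random.Generator, category: Category) -> str:
    """Draw a peptide whose (−1, −3) residues realize the category."""
    length = _randint(rng, (6, 12))
    interior = "".join(_choice(rng, PEPTIDE_INTERIOR_ALPHABET) for _ in range(length - 3))
    if category is Category.L_TYPE:
        a, b = "F", _choice(rng, LEU_LIKE)
    elif category is Category.F_TYPE:
        a, b = "F", _choice(rng, PHE_LIKE)
    elif category is Category.FXL_TYPE:
        a, b = _choice(rng, "LM"), _choice(rng, PHE_LIKE)
    elif category is Category.LXL_TYPE:
        a, b = _choice(rng, "LM"), _choice(rng, LEU_LIKE)
    else:
        a, b = _choice(rng, ATYPICAL_TERMINAL), _choice(rng, PEPTIDE_INTERIOR_ALPHABET)
    x = _choice(rng, PEPTIDE_INTERIOR_ALPHABET)
    return interior + b + x + a


def _signal(rng: np.random.Generator, length: int) -> str:
    """M + hydrophobic core + A-x-A cleavage context, length residues."""
    core = "".join(_choice(rng, SIGNAL_CORE_ALPHABET) for _ in range(length - 4))
    return "M" + core + "A" + _choice(rng, "LF") + "A"


def _spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(_choice(rng, SPACER_ALPHABET) for _ in range(length))


def _boundary(rng: np.random.Generator, spec: SyntheticSpec, force_dibasic: bool) -> str:
    if force_dibasic or rng.random() < spec.dibasic_fraction:
        return _choice(rng, DIBASIC)
    return _choice(rng, "KR")


def generate_precursor(
    spec: SyntheticSpec, rng: np.random.Generator, transcript_id: str = "prec"
) -> tuple[str, TruthRecord]:
    """Build one synthetic precursor protein plus its planted truth.

    Layout: signal ⊕ acidic spacer ⊕ KR ⊕ [peptide ⊕ G ⊕ boundary
    (⊕ spacer ⊕ KR)?]×k ⊕ spacer. The first cleavage site sits at
    residue 45 so the heuristic signal-peptide scan (candidate ends
    15–45) never reaches peptide territory.
    """
    k = _randint(rng, spec.peptides_per_precursor)
    sig_len = _randint(rng, spec.signal_len)
    parts: list[str] = [_signal(rng, sig_len)]
    pos = sig_len
    spacer0 = 45 - sig_len
    parts.append(_spacer(rng, spacer0) + "KR")
    pos += spacer0 + 2
    categories = [
        CATEGORY_ORDER[int(i)]
        for i in rng.choice(5, size=k, p=np.asarray(spec.category_mix, dtype=float))
    ]
    planted: list[PlantedPeptide] = []
    boundary_kinds: list[str] = []
    for idx, category in enumerate(categories):
        pep = _peptide_for_category(rng, category)
        planted.append(
            PlantedPeptide(sequence=pep, span=(pos, pos + len(pep)), category=category)
        )
        parts.append(pep + "G")
        pos += len(pep) + 1
        boundary = _boundary(rng, spec, force_dibasic=category is Category.ATYPICAL)
        boundary_kinds.append(boundary)
        parts.append(boundary)
        pos += len(boundary)
        # a monobasic boundary must be followed by a dibasic-terminated
        # spacer, else the next G-terminated peptide would fuse with this
        # one in the dibasic-only extraction pass
        mono = len(boundary) == 1
        if idx < k - 1 and (mono or rng.random() < 0.5):
            gap = _randint(rng, (4, 10))
            parts.append(_spacer(rng, gap) + "KR")
            pos += gap + 2
    parts.append(_spacer(rng, _randint(rng, (5, 15))))
    protein = "".join(parts)
    truth = TruthRecord(
        transcript_id=transcript_id,
        protein=protein,
        signal_span=(0, sig_len),
        peptides=tuple(planted),
        boundary_kinds=tuple(boundary_kinds),
    )
    return protein, truth


def reverse_translate(
    protein: str,
    rng: np.random.Generator,
    utr_len: tuple[int, int] = (0, 0),
    max_attempts: int = 20,
) -> str:
    """Encode a protein as a transcript with random synonymous codons.

    The coding sequence is the protein's codons followed by a stop;
    random UTRs are attached on both sides. UTRs are resampled if they
    would create an anchored ORF longer than the planted one, so the
    longest-ORF convention always recovers ``protein`` (requires the
    protein to start with M, as every precursor does).
    """
    from .orf import longest_orf_protein  # local import to avoid cycle

    for _ in range(max_attempts):
        # resample codons too: a chance reverse-strand ORF inside the CDS
        # can only be removed by synonymous recoding, not by new UTRs
        cds = "".join(_choice(rng, _CODONS_BY_AA[aa]) for aa in protein) + _choice(rng, STOPS)
        utr5 = "".join(_choice(rng, "ACGT") for _ in range(_randint(rng, utr_len)))
        utr3 = "".join(_choice(rng, "ACGT") for _ in range(_randint(rng, utr_len)))
        transcript = utr5 + cds + utr3
        if not protein.startswith("M"):
            return transcript
        if longest_orf_protein(transcript) == protein:
            return transcript
    raise RuntimeError("could not place UTRs without disturbing the planted ORF")


def _mutate(nt: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return nt
    bases = "ACGT"
    out = list(nt)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _choice(rng, bases.replace(out[i], "") if out[i] in bases else bases)
    return "".join(out)


def generate_transcriptome(
    spec: SyntheticSpec,
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Precursor transcripts plus composition-matched decoys.

    Decoys are per-base shuffles of randomly chosen precursor
    transcripts: same nucleotide composition, no planted architecture.
    Substitution noise is applied after planting, to precursor
    transcripts only (truth records keep the noise-free protein).
    """
    rng = np.random.default_rng(spec.seed)
    records: list[SequenceRecord] = []
    truths: list[TruthRecord] = []
    clean_transcripts: list[str] = []
    for i in range(spec.n_precursors):
        tid = f"prec{i + 1:04d}"
        protein, truth = generate_precursor(spec, rng, transcript_id=tid)
        transcript = reverse_translate(protein, rng, utr_len=spec.utr_len)
        clean_transcripts.append(transcript)
        transcript = _mutate(transcript, spec.substitution_rate, rng)
        records.append(SequenceRecord(id=tid, seq=transcript, alphabet_kind="nucleotide"))
        truths.append(truth)
    for i in range(spec.n_decoys):
        if not clean_transcripts:
            raise ValueError("decoys require at least one precursor transcript as template")
        template = clean_transcripts[int(rng.integers(len(clean_transcripts)))]
        shuffled = "".join(np.asarray(list(template))[rng.permutation(len(template))])
        records.append(
            SequenceRecord(id=f"decoy{i + 1:04d}", seq=shuffled, alphabet_kind="nucleotide")
        )
    return records, truths


def truth_to_tsv(truths: Sequence[TruthRecord]) -> str:
    """Truth table TSV: transcript_id, ordinal, sequence, category, start, end."""
    lines = ["transcript_id\tordinal\tsequence\tcategory\tstart\tend"]
    for t in truths:
        for i, p in enumerate(t.peptides, 1):
            lines.append(
                f"{t.transcript_id}\t{i}\t{p.sequence}\t{p.category.value}"
                f"\t{p.span[0]}\t{p.span[1]}"
            )
    return "\n".join(lines) + "\n"


def truth_to_json(truths: Sequence[TruthRecord]) -> str:
    return json.dumps(
        [
            {
                "transcript_id": t.transcript_id,
                "protein": t.protein,
                "signal_span": list(t.signal_span),
                "boundary_kinds": list(t.boundary_kinds),
                "peptides": [
                    {
                        "ordinal": i,
                        "sequence": p.sequence,
                        "span": list(p.span),
                        "category": p.category.value,
                        "amidated": p.amidated,
                    }
                    for i, p in enumerate(t.peptides, 1)
                ],
            }
            for t in truths
        ],
        indent=2,
    )
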