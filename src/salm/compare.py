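"""Permissive short-peptide homology search and precursor comparison.

Neuropeptides are too short for default database-search significance
thresholds — the queries here are 5–30 residue peptides — so the search
is deliberately permissive: a Smith–Waterman local aligner with affine
gaps whose reporting floor defaults to a fraction of the query's
self-score rather than an E-value (database-size statistics are out of
scope for contig-scale scans). Precursor-level comparison uses global
Needleman–Wunsch alignment, ordinal peptide mapping, and a
gene-structure signature that distinguishes L-type from F-type
SALMFamide genes by the layout of the first protein-coding exon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .orf import _frame_pos_to_nt_span, six_frame_translate
from .seqio import GeneModel, SequenceRecord

if TYPE_CHECKING:  # pragma: no cover
    from .annotate import MaturePeptide, PrecursorAnnotation

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62_dict() -> dict[tuple[str, str], int]:
    """BLOSUM62 as a plain symmetric dict over the matrix alphabet."""
    alpha = _BLOSUM62.alphabet
    return {
        (a, b): int(_BLOSUM62[a, b]) for a in alpha for b in alpha
    }


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    A gap of length k costs ``gap_open + (k − 1) * gap_extend``.
    ``min_report_score`` is an absolute raw-score floor for hits; when
    None, a per-query floor of ``self_score_fraction`` of the query's
    self-alignment score is used (the permissive-search default).
    """

    matrix: dict[tuple[str, str], int] = field(default_factory=blosum62_dict)
    gap_open: int = -11
    gap_extend: int = -1
    min_report_score: int | None = None
    self_score_fraction: float = 0.6

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")

    def score(self, a: str, b: str) -> int:
        return self.matrix.get((a, b), self.matrix.get((b, a), -4))

    def self_score(self, seq: str) -> int:
        return sum(self.score(c, c) for c in seq)

    def report_floor(self, query: str) -> int:
        if self.min_report_score is not None:
            return self.min_report_score
        return math.ceil(self.self_score_fraction * self.self_score(query))


@dataclass(frozen=True)
class Alignment:
    """A pairwise alignment with traceback-derived identity."""

    score: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    aligned_query: str
    aligned_target: str
    identity: float

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)


@dataclass(frozen=True)
class Hit:
    query_id: str
    target_id: str
    frame: int
    target_nt_span: tuple[int, int]
    aligned_query_span: tuple[int, int]
    score: int
    identity: float


class StructureSignature(Enum):
    L_SIGNATURE = "L_SIGNATURE"
    F_SIGNATURE = "F_SIGNATURE"
    UNDETERMINED = "UNDETERMINED"


_DIAG, _UP, _LEFT = 1, 2, 3


def _identity(a: str, b: str) -> float:
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return matches / len(a) if a else 0.0


def local_align(query: str, target: str, scheme: ScoringScheme | None = None) -> Alignment | None:
    """Optimal Smith–Waterman local alignment with affine gaps (Gotoh).

    Ties in the traceback prefer diagonal, then up (gap in target), then
    left. Returns None when the optimal score is below the scheme's
    reporting floor for this query, or when no positive-scoring local
    alignment exists.
    """
    scheme = scheme or ScoringScheme()
    if not query or not target:
        raise ValueError("sequences must be non-empty")
    n, m = len(query), len(target)
    NEG = -(10**9)
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in query (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in target (up)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 up, 3 left
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 open(from H), 0 extend
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    best, best_ij = 0, (0, 0)
    for i in range(1, n + 1):
        qi = query[i - 1]
        for j in range(1, m + 1):
            e_open, e_ext = H[i, j - 1] + go, E[i, j - 1] + ge
            E[i, j], ptrE[i, j] = (e_open, 1) if e_open >= e_ext else (e_ext, 0)
            f_open, f_ext = H[i - 1, j] + go, F[i - 1, j] + ge
            F[i, j], ptrF[i, j] = (f_open, 1) if f_open >= f_ext else (f_ext, 0)
            diag = H[i - 1, j - 1] + scheme.score(qi, target[j - 1])
            h, p = 0, 0
            if diag >= h and diag >= F[i, j] and diag >= E[i, j]:
                h, p = diag, 1
            elif F[i, j] >= h and F[i, j] >= E[i, j]:
                h, p = F[i, j], 2
            elif E[i, j] >= h:
                h, p = E[i, j], 3
            if h <= 0:
                h, p = 0, 0
            H[i, j], ptrH[i, j] = h, p
            if h > best:
                best, best_ij = h, (i, j)
    if best <= 0 or best < scheme.report_floor(query):
        return None
    i, j = best_ij
    aq: list[str] = []
    at: list[str] = []
    state = "H"
    while not (state == "H" and ptrH[i, j] == 0):
        if state == "H":
            p = ptrH[i, j]
            if p == 1:
                aq.append(query[i - 1])
                at.append(target[j - 1])
                i, j = i - 1, j - 1
            elif p == 2:
                state = "F"
            else:
                state = "E"
        elif state == "F":
            aq.append(query[i - 1])
            at.append("-")
            if ptrF[i, j] == 1:
                state = "H"
            i -= 1
        else:
            aq.append("-")
            at.append(target[j - 1])
            if ptrE[i, j] == 1:
                state = "H"
            j -= 1
    aq_s, at_s = "".join(reversed(aq)), "".join(reversed(at))
    return Alignment(
        score=int(best),
        query_span=(i, best_ij[0]),
        target_span=(j, best_ij[1]),
        aligned_query=aq_s,
        aligned_target=at_s,
        identity=_identity(aq_s, at_s),
    )


def global_align(a: str, b: str, scheme: ScoringScheme | None = None) -> Alignment:
    """Needleman–Wunsch global alignment with affine gaps (Gotoh)."""
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    n, m = len(a), len(b)
    NEG = -(10**9)
    go, ge = scheme.gap_open, scheme.gap_extend
    M = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in a (left)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)  # gap in b (up)
    # pointers: previous state 1=M, 2=F, 3=E, 0=origin
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0
    for j in range(1, m + 1):
        E[0, j] = go + (j - 1) * ge
        ptrE[0, j] = 1 if j == 1 else 3
    for i in range(1, n + 1):
        F[i, 0] = go + (i - 1) * ge
        ptrF[i, 0] = 1 if i == 1 else 2
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            cands = (
                (M[i, j - 1] + go, 1),
                (F[i, j - 1] + go, 2),
                (E[i, j - 1] + ge, 3),
            )
            E[i, j], ptrE[i, j] = max(cands, key=lambda t: (t[0], -t[1]))
            cands = (
                (M[i - 1, j] + go, 1),
                (F[i - 1, j] + ge, 2),
                (E[i - 1, j] + go, 3),
            )
            F[i, j], ptrF[i, j] = max(cands, key=lambda t: (t[0], -t[1]))
            s = scheme.score(ai, b[j - 1])
            cands = (
                (M[i - 1, j - 1] + s, 1),
                (F[i - 1, j - 1] + s, 2),
                (E[i - 1, j - 1] + s, 3),
            )
            ptr = max(cands, key=lambda t: (t[0], -t[1]))
            M[i, j], ptrM[i, j] = ptr
    finals = ((M[n, m], "M"), (F[n, m], "F"), (E[n, m], "E"))
    score, state = max(finals, key=lambda t: (t[0], t[1]))
    score = int(score)
    i, j = n, m
    aq: list[str] = []
    at: list[str] = []
    while (i, j) != (0, 0):
        if state == "M":
            aq.append(a[i - 1])
            at.append(b[j - 1])
            prev = ptrM[i, j]
            i, j = i - 1, j - 1
        elif state == "F":
            aq.append(a[i - 1])
            at.append("-")
            prev = ptrF[i, j]
            i -= 1
        else:
            aq.append("-")
            at.append(b[j - 1])
            prev = ptrE[i, j]
            j -= 1
        state = {1: "M", 2: "F", 3: "E"}[int(prev)] if prev else "M"
    aq_s, at_s = "".join(reversed(aq)), "".join(reversed(at))
    return Alignment(
        score=score,
        query_span=(0, n),
        target_span=(0, m),
        aligned_query=aq_s,
        aligned_target=at_s,
        identity=_identity(aq_s, at_s),
    )


def scan_transcriptome(
    queries: Sequence[SequenceRecord],
    transcripts: Sequence[SequenceRecord],
    scheme: ScoringScheme | None = None,
) -> list[Hit]:
    """Align short peptide queries against all six frames of every transcript.

    One optimal local alignment is attempted per query × transcript ×
    frame; alignments at or above the reporting floor become hits,
    sorted by score descending with ties by (target_id, frame).
    """
    scheme = scheme or ScoringScheme()
    hits: list[Hit] = []
    for query in queries:
        if len(query.seq) > 30:
            raise ValueError(f"query {query.id} longer than 30 aa; not a short peptide")
        floor = scheme.report_floor(query.seq)
        for tr in transcripts:
            if len(tr.seq) < 3:
                continue
            frames = six_frame_translate(tr.seq)
            for frame, prot in frames.items():
                if not prot:
                    continue
                aln = local_align(query.seq, prot, scheme)
                if aln is None or aln.score < floor:
                    continue
                hits.append(
                    Hit(
                        query_id=query.id,
                        target_id=tr.id,
                        frame=frame,
                        target_nt_span=_frame_pos_to_nt_span(
                            frame, len(tr.seq), aln.target_span[0], aln.target_span[1]
                        ),
                        aligned_query_span=aln.query_span,
                        score=aln.score,
                        identity=aln.identity,
                    )
                )
    hits.sort(key=lambda h: (-h.score, h.target_id, h.frame))
    return hits


def hits_to_tsv(hits: Iterable[Hit]) -> str:
    """Hits as TSV: query, target, frame, nt_start, nt_end, q_start, q_end, score, identity."""
    header = "query\ttarget\tframe\tnt_start\tnt_end\tq_start\tq_end\tscore\tidentity"
    lines = [header]
    for h in hits:
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        h.query_id,
                        h.target_id,
                        h.frame,
                        h.target_nt_span[0],
                        h.target_nt_span[1],
                        h.aligned_query_span[0],
                        h.aligned_query_span[1],
                        h.score,
                        f"{h.identity:.4f}",
                    ],
                )
            )
        )
    return "\n".join(lines) + "\n"


def align_precursors(
    a: "PrecursorAnnotation", b: "PrecursorAnnotation", scheme: ScoringScheme | None = None
) -> Alignment:
    """Global alignment of two precursor proteins with identity fraction."""
    return global_align(a.record.seq, b.record.seq, scheme)


@dataclass(frozen=True)
class PeptidePair:
    ordinal: int
    peptide_a: "MaturePeptide | None"
    peptide_b: "MaturePeptide | None"
    same_category: bool


def map_peptide_positions(
    a: "PrecursorAnnotation", b: "PrecursorAnnotation"
) -> list[PeptidePair]:
    """Pair peptides of two precursors by ordinal position.

    Cross-species comparisons in this family are positional: homologous
    peptides occupy equivalent positions in the precursor, so pairing is
    by ordinal, not by alignment. Unpaired trailing peptides are
    reported with an absent partner (``same_category=False``).
    """
    if not a.peptides or not b.peptides:
        raise ValueError("both precursors must have at least one peptide")
    pairs: list[PeptidePair] = []
    for k in range(max(len(a.peptides), len(b.peptides))):
        pa = a.peptides[k] if k < len(a.peptides) else None
        pb = b.peptides[k] if k < len(b.peptides) else None
        same = (
            pa is not None
            and pb is not None
            and pa.category is not None
            and pb.category is not None
            and pa.category.category == pb.category.category
        )
        pairs.append(PeptidePair(ordinal=k + 1, peptide_a=pa, peptide_b=pb, same_category=same))
    return pairs


def classify_gene_structure(model: GeneModel) -> StructureSignature:
    """L-vs-F gene-structure signature from the first protein-coding exon.

    L-type SALMFamide genes carry the 5' non-coding region and the start
    codon on the same exon; F-type genes start the CDS exactly at an
    exon boundary preceded by at least one wholly non-coding exon.
    Strand-flip invariant: positions are interpreted in transcription
    order.
    """
    cds_start, cds_end = model.cds
    first_coding_idx = None
    for idx, (s, e) in enumerate(model.exons):
        if s < cds_end and e > cds_start:
            first_coding_idx = idx
            break
    if first_coding_idx is None:
        raise ValueError(f"gene {model.gene_id}: CDS overlaps no exon")
    s, e = model.exons[first_coding_idx]
    if model.strand == "+":
        has_5p_utr_in_exon = s < cds_start
        cds_at_exon_start = s == cds_start
    else:
        has_5p_utr_in_exon = e > cds_end
        cds_at_exon_start = e == cds_end
    if has_5p_utr_in_exon:
        return StructureSignature.L_SIGNATURE
    if cds_at_exon_start and first_coding_idx >= 1:
        return StructureSignature.F_SIGNATURE
    return StructureSignature.UNDETERMINED
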