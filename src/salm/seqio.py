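"""Sequence and gene-model I/O.

Core record types used throughout the pipeline, FASTA reading/writing
(via Biopython) and a GFF3-subset reader for exon/CDS gene models.

Coordinates are 0-based half-open everywhere in memory; rendered reports
convert to 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX*")

AlphabetKind = Literal["nucleotide", "protein"]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide or protein sequence.

    ``seq`` is stored uppercase. ``N`` (nucleotide) and ``X`` (protein)
    denote unknown residues; they never match any motif position.
    """

    id: str
    seq: str
    alphabet_kind: AlphabetKind
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"record id must be a non-empty token, got {self.id!r}")
        if not self.seq:
            raise ValueError(f"record {self.id}: empty sequence")
        alphabet = (
            NUCLEOTIDE_ALPHABET if self.alphabet_kind == "nucleotide" else PROTEIN_ALPHABET
        )
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"record {self.id}: illegal {self.alphabet_kind} residue(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS layout of a gene.

    ``exons`` are genomic (start, end) intervals sorted 5'→3' in
    *transcription* order (descending genomic coordinate on the minus
    strand). ``cds`` is the single genomic interval from the first to the
    last coding base.
    """

    gene_id: str
    strand: Literal["+", "-"]
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        for start, end in self.exons:
            if start >= end:
                raise ValueError(f"gene {self.gene_id}: empty exon ({start}, {end})")
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        expected = tuple(genomic) if self.strand == "+" else tuple(genomic[::-1])
        if self.exons != expected:
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcription order for "
                f"strand {self.strand}"
            )
        cs, ce = self.cds
        if cs >= ce:
            raise ValueError(f"gene {self.gene_id}: empty CDS")
        covered = sum(max(0, min(ce, e) - max(cs, s)) for s, e in self.exons)
        exonic_span = any(s <= cs < e for s, e in self.exons) and any(
            s < ce <= e for s, e in self.exons
        )
        if not exonic_span or covered == 0:
            raise ValueError(f"gene {self.gene_id}: CDS not contained in exon union")


def _alphabet_of(seq: str, declared: AlphabetKind | None) -> AlphabetKind:
    if declared is not None:
        return declared
    return "nucleotide" if set(seq) <= NUCLEOTIDE_ALPHABET else "protein"


def read_fasta(path: str | Path, alphabet: AlphabetKind | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased; record order is preserved. When ``alphabet``
    is None each record's alphabet is inferred (ACGTN-only → nucleotide).
    Duplicate ids or illegal residues raise :class:`ParseError` naming the
    offending record.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq).upper()
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r} (record {i + 1})")
        seen.add(rec.id)
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    seq=seq,
                    alphabet_kind=_alphabet_of(seq, alphabet),
                    description=rec.description[len(rec.id) :].strip(),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: record {i + 1}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA. Round-trips through :func:`read_fasta`."""
    if width < 1:
        raise ValueError("width must be positive")
    path = Path(path)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(
            SeqRecord(Seq(r.seq), id=r.id, description=r.description) for r in records
        )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a GFF3-like file into gene models.

    Only ``exon`` and ``CDS`` features carrying a gene id attribute
    (``gene_id=`` or ``Parent=``/``ID=``) are consumed; every other feature
    type is ignored. Multiple CDS segments per gene are merged into their
    genomic envelope. Output is deterministic: sorted by gene id.
    """
    path = Path(path)
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    strands: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            ftype, start_s, end_s, strand, attrs = (
                fields[2],
                fields[3],
                fields[4],
                fields[6],
                fields[8],
            )
            if ftype not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start_s) - 1, int(end_s)  # GFF is 1-based inclusive
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            gene_id = _gene_id_from_attrs(attrs)
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: {ftype} feature lacks a gene id")
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: strand must be + or -")
            prev = strands.setdefault(gene_id, strand)
            if prev != strand:
                raise ParseError(f"{path}:{lineno}: conflicting strands for {gene_id}")
            (exons if ftype == "exon" else cds).setdefault(gene_id, []).append((start, end))

    models = []
    for gene_id in sorted(exons):
        if gene_id not in cds:
            continue
        strand = strands[gene_id]
        ordered = sorted(exons[gene_id])
        if strand == "-":
            ordered = ordered[::-1]
        cds_env = (min(s for s, _ in cds[gene_id]), max(e for _, e in cds[gene_id]))
        try:
            models.append(
                GeneModel(gene_id=gene_id, strand=strand, exons=tuple(ordered), cds=cds_env)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: gene {gene_id}: {exc}") from exc
    return models


def _gene_id_from_attrs(attrs: str) -> str | None:
    kv = {}
    for part in attrs.replace(";", " ;").split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            kv[k.strip()] = v.strip()
    for key in ("gene_id", "Parent", "ID"):
        if key in kv:
            return kv[key]
    return None
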