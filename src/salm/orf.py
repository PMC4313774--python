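"""Six-frame translation and open-reading-frame selection.

Transcript contigs from de novo assemblies have no annotated coding
sequence, so candidate precursor proteins are obtained by translating all
six reading frames and selecting ORFs. Anchored ORFs run from a start
codon (ATG) to the first in-frame stop; unanchored ORFs are maximal
stop-free stretches, useful for truncated contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

FRAMES = (1, 2, 3, -1, -2, -3)


class NoOrfError(ValueError):
    """Raised when a transcript contains no anchored ORF."""


@dataclass(frozen=True)
class OrfRegion:
    """An open reading frame located on a transcript.

    ``nt_span`` is on the forward strand, 0-based half-open, and includes
    the closing stop codon when ``has_stop`` is true. ``protein`` never
    contains stop characters.
    """

    source_id: str
    frame: int
    nt_span: tuple[int, int]
    protein: str
    has_stop: bool

    def __post_init__(self) -> None:
        start, end = self.nt_span
        expected = (end - start) // 3 - (1 if self.has_stop else 0)
        if len(self.protein) != expected:
            raise ValueError(
                f"protein length {len(self.protein)} inconsistent with span "
                f"{self.nt_span} (has_stop={self.has_stop})"
            )
        if "*" in self.protein:
            raise ValueError("internal stop in ORF protein")


def reverse_complement(nt: str) -> str:
    return str(Seq(nt).reverse_complement())


def six_frame_translate(nt: str) -> dict[int, str]:
    """Translate all six reading frames with the standard genetic code.

    Returns a mapping frame → protein string with stops rendered as ``*``.
    Frames −1..−3 read the reverse complement. Incomplete terminal codons
    are dropped, not padded.
    """
    if len(nt) < 3:
        raise ValueError("nucleotide sequence shorter than one codon")
    nt = nt.upper()
    rc = reverse_complement(nt)
    out: dict[int, str] = {}
    for frame in FRAMES:
        strand_seq = nt if frame > 0 else rc
        offset = abs(frame) - 1
        coding = strand_seq[offset : offset + 3 * ((len(strand_seq) - offset) // 3)]
        out[frame] = str(Seq(coding).translate())
    return out


def _frame_pos_to_nt_span(frame: int, seq_len: int, aa_start: int, aa_end: int) -> tuple[int, int]:
    """Map a protein interval in a frame's translation to forward-strand nt."""
    offset = abs(frame) - 1
    if frame > 0:
        return (offset + 3 * aa_start, offset + 3 * aa_end)
    # positions counted from the 3' end on the forward strand
    return (seq_len - offset - 3 * aa_end, seq_len - offset - 3 * aa_start)


def find_orfs(
    nt: str,
    min_aa: int = 1,
    anchored: bool = True,
    source_id: str = "",
) -> list[OrfRegion]:
    """Locate ORFs in all six frames.

    Anchored mode reports, for every ATG, the ORF running to the first
    in-frame stop (or the end of the last complete codon, flagged
    ``has_stop=False``). Unanchored mode reports maximal stop-free
    stretches. Results are sorted by protein length descending, ties by
    (frame, start) ascending.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be positive")
    translations = six_frame_translate(nt)
    orfs: list[OrfRegion] = []
    for frame in FRAMES:
        prot = translations[frame]
        if anchored:
            stops = [i for i, aa in enumerate(prot) if aa == "*"]
            for m in (i for i, aa in enumerate(prot) if aa == "M"):
                stop = next((s for s in stops if s > m), None)
                if stop is None:
                    aa_end, has_stop, pep = len(prot), False, prot[m:]
                else:
                    aa_end, has_stop, pep = stop + 1, True, prot[m:stop]
                if len(pep) >= min_aa:
                    orfs.append(
                        OrfRegion(
                            source_id=source_id,
                            frame=frame,
                            nt_span=_frame_pos_to_nt_span(frame, len(nt), m, aa_end),
                            protein=pep,
                            has_stop=has_stop,
                        )
                    )
        else:
            start = 0
            for i, aa in enumerate(prot + "*"):
                if aa == "*":
                    if i - start >= min_aa:
                        has_stop = i < len(prot)
                        orfs.append(
                            OrfRegion(
                                source_id=source_id,
                                frame=frame,
                                nt_span=_frame_pos_to_nt_span(
                                    frame, len(nt), start, i + (1 if has_stop else 0)
                                ),
                                protein=prot[start:i],
                                has_stop=has_stop,
                            )
                        )
                    start = i + 1
    # ties: + strand before −, then earliest forward-strand start, then frame
    orfs.sort(
        key=lambda o: (-len(o.protein), 0 if o.frame > 0 else 1, o.nt_span[0], abs(o.frame))
    )
    return orfs


def longest_orf_protein(nt: str, source_id: str = "") -> str:
    """Protein of the longest anchored ORF (stop excluded from length).

    Exact-length ties are broken by earliest start on the + strand, then
    the − strand. Raises :class:`NoOrfError` when no ATG-anchored ORF
    exists.
    """
    orfs = find_orfs(nt, min_aa=1, anchored=True, source_id=source_id)
    if not orfs:
        raise NoOrfError(f"no anchored ORF in {source_id or 'sequence'}")
    return orfs[0].protein
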