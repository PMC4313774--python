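"""Synthetic stand-in precursors and gene models for published sequences.

The deposited precursor cDNAs and the supplementary-figure protein
sequences behind the published annotations are not redistributable with
this package, so this module constructs SYNTHETIC stand-ins: precursor
proteins (and reverse-translated cDNAs) that reproduce every
architecture fact the primary literature states — protein and signal
lengths, peptide counts, per-category compositions, printed peptide
sequences and C-terminal pentapeptides, mono/dibasic boundary usage —
with invented spacer/linker residues everywhere the true residues are
not printed. They exercise the pipeline end to end; they are not the
deposited sequences.

Gene-model stand-ins likewise reproduce the published exon/CDS layouts
(L-type genes: first protein-coding exon carries the 5' UTR; F-type
genes: 5' non-coding exon(s), CDS starting exactly at an exon boundary)
with invented coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .motif import Category
from .peptides import S1, S2
from .seqio import GeneModel, SequenceRecord
from .synth import SPACER_ALPHABET, _peptide_for_category, reverse_translate

_SPACER_CYCLE = SPACER_ALPHABET


def _spacer(length: int) -> str:
    return "".join(_SPACER_CYCLE[i % len(_SPACER_CYCLE)] for i in range(length))


def _signal(length: int) -> str:
    # M + Leu core + A-L-A cleavage context; heuristic end lands at `length`
    return "M" + "L" * (length - 4) + "ALA"


@dataclass(frozen=True)
class StandinSpec:
    record_id: str
    signal_len: int
    # (sequence, boundary) pairs; boundary "KR"/"RR"/… or "K"/"R" (monobasic)
    peptides: tuple[tuple[str, str], ...]
    total_len: int | None = None  # pad C-terminal spacer to this length


def build_standin(spec: StandinSpec) -> SequenceRecord:
    """Assemble a stand-in precursor protein from its architecture spec.

    Layout: signal ⊕ spacer ⊕ KR ⊕ [peptide ⊕ G ⊕ boundary (⊕ spacer ⊕
    KR after a monobasic boundary)] × k ⊕ C-terminal spacer. The first
    cleavage site sits at residue 45 so the signal-peptide heuristic
    never scores peptide residues.
    """
    parts = [_signal(spec.signal_len), _spacer(45 - spec.signal_len), "KR"]
    for i, (pep, boundary) in enumerate(spec.peptides):
        parts.append(pep + "G")
        parts.append(boundary)
        if len(boundary) == 1 and i < len(spec.peptides) - 1:
            parts.append(_spacer(6) + "KR")
    body = "".join(parts)
    if spec.total_len is None:
        tail = 20
    else:
        tail = spec.total_len - len(body)
        if tail < 5:
            raise ValueError(
                f"{spec.record_id}: architecture ({len(body)} aa) exceeds "
                f"total_len {spec.total_len}"
            )
    protein = body + _spacer(tail)
    return SequenceRecord(id=spec.record_id, seq=protein, alphabet_kind="protein")


def _generated(category: Category, n: int, seed: int) -> list[str]:
    """Deterministic plausible peptides of one category (invented residues)."""
    rng = np.random.default_rng(seed)
    return [_peptide_for_category(rng, category) for _ in range(n)]


def _standin_specs() -> dict[str, StandinSpec]:
    L, F, FXL, LXL = (
        Category.L_TYPE,
        Category.F_TYPE,
        Category.FXL_TYPE,
        Category.LXL_TYPE,
    )
    specs: dict[str, StandinSpec] = {}

    # A. mediterranea single precursor: 370 aa, 22-residue signal, 12
    # peptides — 2 LxF, 1 FxF, 5 FxL, 4 LxL, all dibasic-bounded.
    amed_cats = [L, FXL, LXL, FXL, LXL, F, FXL, LXL, FXL, LXL, FXL, L]
    rng = np.random.default_rng(20150202)
    amed_peps = [_peptide_for_category(rng, c) for c in amed_cats]
    specs["Amed-SALMFa-prec"] = StandinSpec(
        record_id="Amed-SALMFa-prec",
        signal_len=22,
        peptides=tuple((p, "KR") for p in amed_peps),
        total_len=370,
    )

    # O. victoriae F-type: 310 aa, 23-residue signal, 12 peptides,
    # 11 F-type + 1 L-type (ordinal 6), dibasic-bounded.
    ovf_cats = [F] * 5 + [L] + [F] * 6
    rng = np.random.default_rng(979352)
    ovf_peps = [_peptide_for_category(rng, c) for c in ovf_cats]
    specs["Ovic-F-prec"] = StandinSpec(
        record_id="Ovic-F-prec",
        signal_len=23,
        peptides=tuple((p, "KR") for p in ovf_peps),
        total_len=310,
    )

    # O. victoriae L-type: 169 aa, 20-residue signal, 4 peptides with the
    # printed C-termini (SGLTFamide dodecapeptide, SGLMQamide and
    # TGFMMamide 11-mers, SGMTFamide 14-mer); one monobasic boundary.
    specs["Ovic-L-prec"] = StandinSpec(
        record_id="Ovic-L-prec",
        signal_len=20,
        peptides=(
            ("AGLDQLNSGLTF", "R"),  # canonical SxLxFamide, 12 aa
            ("SRLPFHSGLMQ", "KR"),  # atypical C-terminal Gln, 11 aa
            ("ADSPDATGFMM", "KR"),  # FxMamide → FxL category, 11 aa
            ("ADQNPGTDASGMTF", "KR"),  # L-type-like SxMxFamide, 14 aa
        ),
        total_len=169,
    )

    # P. miniata L-type: 212 aa, 7 L-type peptides including S1.
    pml = [S1] + _generated(L, 6, seed=775329)
    specs["Pmin-L-prec"] = StandinSpec(
        record_id="Pmin-L-prec",
        signal_len=22,
        peptides=tuple((p, "KR") for p in pml),
        total_len=212,
    )

    # P. miniata F-type: 258 aa, 8 F-type + 1 S2-like L-type (ordinal 9).
    pmf = _generated(F, 8, seed=770521) + [S2]
    specs["Pmin-F-prec"] = StandinSpec(
        record_id="Pmin-F-prec",
        signal_len=22,
        peptides=tuple((p, "KR") for p in pmf),
        total_len=258,
    )

    # S. purpuratus: L-type with one canonical L and one SxIxF-like;
    # F-type with seven F-type peptides.
    specs["Spur-L-prec"] = StandinSpec(
        record_id="Spur-L-prec",
        signal_len=20,
        peptides=(("PHSALTF", "KR"), ("DAGHSAIEF", "KR")),
    )
    specs["Spur-F-prec"] = StandinSpec(
        record_id="Spur-F-prec",
        signal_len=21,
        peptides=tuple((p, "KR") for p in _generated(F, 7, seed=7)),
    )

    # A. japonicus: L-type with three L/L-like; F-type with five F-type,
    # three L-type and the printed atypical GVPPYVVKVTYamide.
    specs["Ajap-L-prec"] = StandinSpec(
        record_id="Ajap-L-prec",
        signal_len=22,
        peptides=tuple((p, "KR") for p in _generated(L, 3, seed=16)),
    )
    ajf = _generated(F, 5, seed=17) + _generated(L, 3, seed=18) + ["GVPPYVVKVTY"]
    specs["Ajap-F-prec"] = StandinSpec(
        record_id="Ajap-F-prec",
        signal_len=22,
        peptides=tuple((p, "KR") for p in ajf),
    )
    return specs


def standin_precursor(record_id: str) -> SequenceRecord:
    """One stand-in precursor protein by id (see :func:`standin_ids`)."""
    return build_standin(_standin_specs()[record_id])


def standin_ids() -> list[str]:
    return list(_standin_specs())


def five_class_precursors() -> list[SequenceRecord]:
    """Stand-in precursor proteins for one species per echinoderm class."""
    return [standin_precursor(rid) for rid in standin_ids()]


def standin_cdnas(seed: int = 0) -> list[SequenceRecord]:
    """Reverse-translated stand-in cDNAs for the three cloned precursors.

    Order: A. mediterranea precursor (370 aa), O. victoriae F-type
    (310 aa), O. victoriae L-type (169 aa).
    """
    rng = np.random.default_rng(seed)
    out = []
    for rid in ("Amed-SALMFa-prec", "Ovic-F-prec", "Ovic-L-prec"):
        protein = standin_precursor(rid).seq
        nt = reverse_translate(protein, rng, utr_len=(60, 200))
        out.append(
            SequenceRecord(id=rid + "-cDNA", seq=nt, alphabet_kind="nucleotide")
        )
    return out


def gene_model_standins() -> dict[str, GeneModel]:
    """Gene models reproducing the published L/F exon-layout contrast.

    L-type genes (two exons, the first carrying both the 5' UTR and the
    start of the CDS) versus F-type genes (one or two wholly non-coding
    5' exons, then an exon whose first codon is the start codon).
    Coordinates are invented; only the layout is faithful.
    """
    return {
        # 2 exons; CDS starts mid-exon 1
        "Pmin-L-gene": GeneModel(
            gene_id="Pmin-L-gene",
            strand="+",
            exons=((0, 500), (1500, 3200)),
            cds=(120, 2100),
        ),
        # two 5' non-coding exons; CDS starts at exon-3 start
        "Pmin-F-gene": GeneModel(
            gene_id="Pmin-F-gene",
            strand="+",
            exons=((0, 180), (800, 950), (2000, 3800)),
            cds=(2000, 2900),
        ),
        # 2 exons; CDS starts mid-exon 1
        "Spur-L-gene": GeneModel(
            gene_id="Spur-L-gene",
            strand="+",
            exons=((0, 420), (1200, 2900)),
            cds=(200, 1900),
        ),
        # one 5' non-coding exon; CDS starts at exon-2 start
        "Spur-F-gene": GeneModel(
            gene_id="Spur-F-gene",
            strand="+",
            exons=((0, 250), (1100, 3000)),
            cds=(1100, 2200),
        ),
    }


def mirror_gene_model(model: GeneModel, chrom_len: int = 10000) -> GeneModel:
    """Strand-flip a gene model with coordinate mirroring (for invariance checks)."""
    def flip(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (chrom_len - e, chrom_len - s)

    return GeneModel(
        gene_id=model.gene_id + "-flipped",
        strand="-" if model.strand == "+" else "+",
        exons=tuple(flip(iv) for iv in model.exons),
        cds=flip(model.cds),
    )
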