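"""SALMFamide peptides with published primary structures.

Mature sequences are stored without the glycine amidation donor; all of
these peptides are C-terminally amidated. S1 and S2 are the Asterias
prototypes of the family; the Holothuria glaberrima pair are L-type and
the Apostichopus japonicus pair are F-type; the last two are precursor
products that fit none of the four C-terminal categories.
"""

from .seqio import SequenceRecord

S1 = "GFNSALMF"  # Gly-Phe-Asn-Ser-Ala-Leu-Met-Phe-NH2
S2 = "SGPYSFNSGLTF"  # Ser-Gly-Pro-Tyr-Ser-Phe-Asn-Ser-Gly-Leu-Thr-Phe-NH2

KNOWN_AMIDATED_PEPTIDES: dict[str, str] = {
    "S1": S1,
    "S2": S2,
    # Holothuria glaberrima (sea cucumber), L-type
    "Hg-SALMFamide-1": "GFSKLYF",
    "Hg-SALMFamide-2": "SGYSVLYF",
    # Apostichopus japonicus (sea cucumber), F-type
    "Aj-SALMFamide-1": "GYSPFMF",
    "Aj-SALMFamide-2": "FKSPFMF",
    # precursor products outside the four categories
    "Ov-SALMFamide-atypical": "SRLPFHSGLMQ",  # O. victoriae, C-terminal Gln
    "Aj-SALMFamide-atypical": "GVPPYVVKVTY",  # A. japonicus, C-terminal Tyr
}


def known_peptide_records() -> list[SequenceRecord]:
    """The published peptides as protein records (mature, amide-less G removed)."""
    return [
        SequenceRecord(id=name, seq=seq, alphabet_kind="protein")
        for name, seq in KNOWN_AMIDATED_PEPTIDES.items()
    ]
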