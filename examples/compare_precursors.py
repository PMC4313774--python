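"""Cross-species precursor comparison and gene-structure signatures.

Homologous peptides occupy equivalent ordinal positions in SALMFamide
precursors, so peptides are paired by position, not by alignment; a
category flip at one position (here FxL vs LxL at ordinal 3) is the
kind of lineage-specific divergence the comparison is meant to surface.
Gene structure gives an orthology signal independent of sequence: L-type
genes carry 5' UTR on the first coding exon, F-type genes do not.
"""

from salm.annotate import annotate_precursor
from salm.compare import align_precursors, classify_gene_structure, map_peptide_positions
from salm.synthetic_standins import (
    StandinSpec,
    build_standin,
    gene_model_standins,
    standin_precursor,
)

a = annotate_precursor(standin_precursor("Ovic-L-prec"))
# a second ophiuroid L-type stand-in whose third peptide ends SAMLLamide
b = annotate_precursor(
    build_standin(
        StandinSpec(
            record_id="Oang-L-prec",
            signal_len=20,
            peptides=(
                ("AGLDQLNSGLAF", "KR"),
                ("SRLPFHSGLMQ", "KR"),
                ("ADSPDSAMLL", "KR"),
                ("ADQNPGTDASGMTF", "KR"),
            ),
            total_len=170,
        )
    )
)

aln = align_precursors(a, b)
print(f"global alignment: score {aln.score}, identity {aln.identity:.2f}")
print(f"\n{'ordinal':<9}{'precursor A':<20}{'precursor B':<20}same category")
for pair in map_peptide_positions(a, b):
    pa = pair.peptide_a.sequence + "amide" if pair.peptide_a else "-"
    pb = pair.peptide_b.sequence + "amide" if pair.peptide_b else "-"
    print(f"{pair.ordinal:<9}{pa:<20}{pb:<20}{pair.same_category}")

print("\ngene-structure signatures (L: 5' UTR on first coding exon):")
for name, model in gene_model_standins().items():
    print(f"  {name}: {classify_gene_structure(model).value}")
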