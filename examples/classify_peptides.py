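"""Classify published SALMFamide peptides and derive the S1/S2 consensus.

The four-way scheme reads the residues at −1 and −3 of the amidated
peptide: LxF (L-type), FxF (F-type), FxL and LxL, with I/M accepted as
leucine-like and Y as phenylalanine-like; everything else is atypical.
"""

from salm.motif import classify_sequence, consensus_motif
from salm.peptides import KNOWN_AMIDATED_PEPTIDES, S1, S2

print(f"{'peptide':<28}{'sequence':<18}{'category':<10}variant")
for name, seq in KNOWN_AMIDATED_PEPTIDES.items():
    cat = classify_sequence(seq, amidated=True)
    variant = "canonical" if cat.canonical else "-like" if cat.category.value != "atypical" else "-"
    print(f"{name:<28}{seq + 'amide':<18}{str(cat.category):<10}{variant}")

# S1 and S2 share a seven-residue C-terminal consensus, the signature
# that originally suggested they arose by gene/intragenic duplication.
print("\nS1/S2 consensus:", consensus_motif([S1, S2]).rendered())
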