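"""Annotate a precursor protein: signal peptide, cleavage sites, peptides.

Uses the synthetic stand-in for the brittle-star L-type precursor
(169 residues, 20-residue signal, four peptides, one monobasic site).
The peptide table shows how a C-terminal Gly marks amidation and how
each peptide's −1/−3 residues determine its category.
"""

from salm.annotate import annotate_precursor
from salm.synthetic_standins import standin_precursor

record = standin_precursor("Ovic-L-prec")
ann = annotate_precursor(record)

print(f"{record.id}: {len(record.seq)} residues")
print(f"signal peptide: residues 1-{ann.signal.end}")
print("cleavage sites:", ", ".join(f"{s.kind}@{s.pos + 1}" for s in ann.sites))
print(f"\n{'#':<3}{'peptide':<20}{'span':<12}{'category':<10}amidated")
for p in ann.peptides:
    span = f"{p.span[0] + 1}-{p.span[1]}"
    print(f"{p.ordinal:<3}{p.sequence + 'amide':<20}{span:<12}{str(p.category.category):<10}{p.amidated}")
print("\ncomposition:", {str(c): n for c, n in ann.composition.items() if n})
print("precursor type call:", ann.type_call.call.value)
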