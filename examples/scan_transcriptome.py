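"""Permissive short-peptide search over a synthetic transcriptome.

Plants one precursor transcript among 50 shuffled decoys, then uses the
eight-residue peptide S1 as a query against all six reading frames of
every transcript. The reporting floor is 60% of the query's self-score
— the package's stand-in for a highly permissive E-value cutoff, needed
because an 8-mer can never reach conventional significance.
"""

import numpy as np

from salm.compare import scan_transcriptome
from salm.peptides import S1
from salm.seqio import SequenceRecord
from salm.synth import reverse_translate
from salm.synthetic_standins import standin_precursor

rng = np.random.default_rng(7)
precursor = standin_precursor("Pmin-L-prec")  # its first peptide is S1
transcript = reverse_translate(precursor.seq, rng, utr_len=(50, 120))
records = [SequenceRecord(id="planted", seq=transcript, alphabet_kind="nucleotide")]
for i in range(50):
    shuffled = "".join(np.asarray(list(transcript))[rng.permutation(len(transcript))])
    records.append(SequenceRecord(id=f"decoy{i:02d}", seq=shuffled, alphabet_kind="nucleotide"))

query = SequenceRecord(id="S1", seq=S1, alphabet_kind="protein")
hits = scan_transcriptome([query], records)

print(f"{len(records)} transcripts scanned, {len(hits)} hit(s) above the floor")
for h in hits[:5]:
    print(
        f"  {h.query_id} -> {h.target_id} frame {h.frame:+d} "
        f"nt {h.target_nt_span[0]}-{h.target_nt_span[1]} "
        f"score {h.score} identity {h.identity:.2f}"
    )
print("\ntop hit is the planted transcript:", hits[0].target_id == "planted")
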