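# salm

Discovery and classification of SALMFamide neuropeptide precursors from
transcriptome sequence data.

SALMFamides are C-terminally amidated neuropeptides found throughout the
phylum Echinodermata (starfish, brittle stars, sea urchins, sea
cucumbers, feather stars), where they act as muscle relaxants. They are
produced from precursor proteins (prepropeptides): an N-terminal signal
peptide followed by multiple peptide copies flanked by monobasic or
dibasic (KR, RR, KK, RK) prohormone-convertase cleavage sites, each
peptide carrying a C-terminal glycine that is converted into an amide.
Family membership and precursor typing are read off the C-terminus of
each amidated peptide: writing the motif as `b-x-a(-NH2)` with `a` at
position −1 and `b` at −3,

| category | a (−1) | b (−3) | example |
|----------|--------|--------|---------|
| LxF (L-type) | F | L (or I/M, "-like") | GFNSALMFamide (S1) |
| FxF (F-type) | F | F (or Y) | GYSPFMFamide |
| FxL | L/M | F/Y | TGFMMamide |
| LxL | L/M | L/I/M | SAMLLamide |

Anything else — including non-amidated peptides — is atypical. A
precursor whose classified peptides are mostly LxF is an L-type
precursor, mostly FxF an F-type precursor; ancestral-type precursors
(as in crinoids) fit neither and are called MIXED.

The package turns the originally manual annotation procedure into an
algorithmic pipeline:

- **orf** — six-frame translation and ORF selection (longest
  ATG-anchored ORF) to obtain candidate precursors from contigs;
- **annotate** — heuristic signal-peptide prediction (Kyte–Doolittle
  hydrophobic core + von Heijne-style (−3,−1) small-residue rule),
  greedy dibasic-site parsing, and two-pass peptide extraction with a
  monobasic rescue gated on amidation and classifiability;
- **motif** — four-way C-terminal classification, wildcard consensus
  motifs (e.g. S1+S2 → `FNSxLxFamide`), precursor type calls;
- **compare** — Smith–Waterman / Needleman–Wunsch affine-gap aligners
  (BLOSUM62, gap open −11 / extend −1), a permissive short-peptide
  transcriptome scan, ordinal peptide mapping between precursors, and
  the L/F gene-structure orthology signature (L-type genes carry 5' UTR
  on the first protein-coding exon; F-type genes start their CDS at an
  exon boundary after non-coding exon(s));
- **synth** — a fully seeded synthetic precursor/transcriptome generator
  with planted ground truth, plus synthetic stand-ins reproducing the
  published precursor architectures;
- **pipeline / cli** — orchestration, composition reports, and a thin
  `salm` command-line wrapper.

## Worked example

```
python examples/annotate_precursor.py
```

```
Ovic-L-prec: 169 residues
signal peptide: residues 1-20
cleavage sites: KR@46, mono_R@61, KR@68, KR@82, KR@96, KR@113

#  peptide             span        category  amidated
1  AGLDQLNSGLTFamide   48-59       LxF       True
2  SRLPFHSGLMQamide    70-80       atypical  True
3  ADSPDATGFMMamide    84-94       FxL       True
4  ADQNPGTDASGMTFamide 98-111      LxF       True

composition: {'LxF': 2, 'FxL': 1, 'atypical': 1}
precursor type call: L_PRECURSOR
```

The 169-residue brittle-star-style precursor yields a 20-residue signal
peptide and four peptides: a canonical L-type dodecapeptide, an unusual
Gln-terminated peptide that no category accepts, an FxL peptide
(TGFMMamide) and an L-type-like SxMxFamide peptide. Two of three
classified peptides are LxF, so the precursor types as L. The second
cleavage site is monobasic (`mono_R@61`): a single arginine honored only
because the peptide it releases is amidated and classifiable.

Other examples: `classify_peptides.py` (the published peptide set and
the S1/S2 consensus), `scan_transcriptome.py` (permissive 8-mer search
against six-frame translations), `compare_precursors.py` (ordinal
peptide mapping and gene-structure signatures), `simulate_and_recover.py`
(benchmark against planted truth). The same operations are available as
`salm annotate|classify|consensus|scan|compare|genestruct|simulate|report`.

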