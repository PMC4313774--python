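# Methods

## The annotation model

A SALMFamide precursor is modelled as

    signal peptide ⊕ { spacer | peptide·G | cleavage site }* 

on a single protein sequence. The pipeline's job, given a protein (or a
transcript from which the longest ATG-anchored ORF is taken), is to
recover the signal span, the cleavage sites, and the mature peptides
with their amidation state, then classify each peptide and type the
precursor. All coordinates are 0-based half-open internally; rendered
reports are 1-based inclusive.

### Signal peptide

Published precursor annotations in this family come from unnamed
signal-peptide predictors, so the package uses a transparent two-part
heuristic rather than attempting to reproduce any specific tool:

1. *hydrophobic core*: some 8-residue window wholly within the first 30
   residues must have mean Kyte–Doolittle hydropathy ≥ 1.6;
2. *cleavage scoring*: every candidate end position 15–45 receives one
   point if the residue at −1 is small (A/G/S/C/T) and one point if the
   residue at −3 is small or aliphatic (A/G/S/C/T/V/I/L) — the
   (−3,−1) rule of classic signal-peptidase models — minus 0.05 per
   residue of distance from position 25; highest score wins, smallest
   end on ties.

If the core test fails the protein has no signal call. Because no
heuristic reproduces published predictor outputs exactly, the
annotation config accepts a per-record override table pinning the
cleavage position; the heuristic is the default path. The bonus values
(+1 per satisfied position) and the 0.05/residue penalty are fixed
conventions of this package.

### Cleavage sites and peptide extraction

Dibasic pairs KR, RR, KK, RK downstream of the signal are sites;
overlapping basic runs (e.g. KRR) are resolved greedily left-to-right,
which makes parsing deterministic (KRRK → KR + RK). Extraction is
two-pass:

- *Pass 1 (dibasic only)*: every inter-site segment — including the
  stretch from signal end to the first site and from the last site to
  the terminus — is a candidate. Stray boundary K/R residues are
  stripped; a terminal G marks the candidate as amidated and is removed
  from the stored sequence; non-amidated candidates are dropped under
  the default `require_amidation=True`; candidates shorter than
  `min_len` (default 5, the shortest published mature motif being a
  pentapeptide) are dropped.
- *Pass 2 (monobasic rescue)*: segments that yielded no peptide are
  re-scanned left to right; a lone K/R is accepted as a site exactly
  when the peptide it would release is amidated *and* classifies into
  one of the four motif categories. Unrestricted monobasic cleavage
  floods false positives; this gate restricts it to cuts that produce
  family members. Rescue only ever adds peptides (monotone
  augmentation): segments already explained by dibasic sites are left
  alone.

Both residues of a dibasic site belong to the site, never to a peptide.

### Classification and typing

The category of an amidated peptide is a pure function of the residues
at −1 (`a`) and −3 (`b`): LxF when a=F and b∈{L,I,M}; FxF when a=F and
b∈{F,Y}; FxL when a∈{L,M} and b∈{F,Y}; LxL when a∈{L,M} and b∈{L,I,M};
otherwise atypical, as is any non-amidated peptide. Leucine-like {L,I,M}
and phenylalanine-like {F,Y} substitution sets follow the family's
published "-like" usage (IxFamide, SxMxFamide, YxFamide, FxMamide,
LxMamide). FxMamide peptides sit in the FxL category: the four-type
scheme groups FxLamide with FxMamide even though running usage sometimes
calls such peptides F-type-like. The `canonical` flag records whether
the strict letter (L/F) matches; only the four-way category feeds
downstream logic. Unknown residues (X) match no motif position.

Precursor typing: among non-atypical peptides, L_PRECURSOR when the LxF
count is strictly greatest and ≥50% of classified peptides, F_PRECURSOR
symmetrically, UNDETERMINED below two classified peptides, else MIXED.
The 50% dominance rule reproduces every published L/F typing while
leaving ancestral-type (crinoid-style) precursors MIXED.

### Detection rule

A record counts as a detected SALMFamide precursor when its annotation
contains at least one classifiable (non-atypical) amidated peptide
(`pipeline.is_putative_precursor`). Family membership is motif-defined,
so a chance Gly-terminated segment in a random ORF — which the
extractor will happily emit as an "amidated peptide" — is not a
detection unless its C-terminus fits the family.

## Alignment and search

The short-peptide search and precursor comparison use an in-package
Gotoh affine-gap dynamic programme (Smith–Waterman local,
Needleman–Wunsch global) with BLOSUM62, gap open −11, gap extend −1 (a
gap of length k costs open + (k−1)·extend). Traceback ties prefer
diagonal, then up, then left, making reported spans deterministic.
Queries are ≤30-residue peptides, far below any meaningful E-value
threshold, so permissiveness is expressed as a raw-score floor: by
default 60% of the query's self-score (an absolute floor can be set
instead). Database-size statistics (Karlin–Altschul) are deliberately
out of scope at contig scale. Hits record the frame and the
forward-strand nucleotide span of the aligned region.

Cross-species peptide comparison is ordinal: homologous peptides occupy
equivalent positions in SALMFamide precursors, so peptides are paired
by rank, not by alignment, and the comparison reports category
agreement per ordinal with unpaired trailing peptides flagged.

Gene-structure signature: locate the first exon overlapping the CDS in
transcription order. If that exon contains ≥1 nt 5' of the CDS start →
L_SIGNATURE; if the CDS starts exactly at the exon's 5' boundary and at
least one wholly non-coding exon precedes it → F_SIGNATURE; otherwise
UNDETERMINED. The rule is strand-flip invariant because positions are
interpreted in transcription order.

## Synthetic data

The generator emulates the precursor architecture the annotator
assumes, with every random draw flowing through one seeded numpy
PCG64 generator (same seed ⇒ bit-identical FASTA and truth table).
Defaults: signal length 18–25; 3–8 peptides per precursor of length
6–12; category mix (0.4, 0.4, 0.1, 0.1, 0) over (LxF, FxF, FxL, LxL,
atypical); dibasic boundary probability 0.8; UTRs of 30–150 nt; 50
decoys per transcriptome; substitution rate 0.

Constructions that keep planted truth exactly recoverable, all
documented simplifications:

- signal = M + hydrophobic {L,I,V,F} core + A-x-A cleavage context; the
  acidic spacer after it is sized so the first cleavage site sits at
  residue 45, the far end of the heuristic's candidate window, making
  the planted signal end the unique score maximum;
- spacers draw from {D,E,N,Q,P,H} — non-basic, non-glycine, not
  (−3,−1)-small — and every non-empty spacer ends at a dibasic site, so
  spacer residues can never fuse onto a peptide;
- a monobasic boundary is always followed by a dibasic-terminated
  spacer: otherwise the next G-terminated peptide would fuse with the
  current one in the dibasic-only pass;
- boundaries after planted atypical peptides are always dibasic, since
  monobasic rescue requires classifiability;
- reverse translation samples synonymous codons uniformly, appends a
  stop and random UTRs, and resamples (codons included) until the
  planted ORF is the longest anchored ORF — chance reverse-strand ORFs
  inside a CDS can only be removed by synonymous recoding.

Decoys are per-base shuffles of precursor transcripts: identical
nucleotide composition, no architecture. Substitution noise, applied
after planting, perturbs precursor transcripts while truth records keep
the noise-free sequences, so recovery-vs-noise curves measure
robustness of the whole pipeline.

What passing on synthetic data does **not** show: real transcriptomes
have fragmented and chimeric contigs, sequencing error, heterozygosity,
spacers that contain basic residues and glycines, signal peptides that
defeat the heuristic, and peptides shorter than `min_len`. The
synthetic results bound the pipeline's algorithmic correctness, not its
field sensitivity.

## Stand-ins for published sequences

`salm.synthetic_standins` builds synthetic precursor proteins (and
reverse-translated cDNAs) that reproduce the published architecture
facts — protein lengths 370/310/169 and 212/258, signal lengths
22/23/20, peptide counts 12/12/4 and 7/9, the 2 LxF + 1 FxF + 5 FxL +
4 LxL crinoid composition, the 11 F + 1 L brittle-star F-type
composition, printed peptides (S1, S2, the sea-cucumber pairs, the two
atypical peptides) and printed C-terminal pentapeptides (SGLTF, SGLMQ,
TGFMM, SGMTF) — while every unprinted residue is invented. Tests and
the acceptance script run the real pipeline on these stand-ins; what
they verify is that the pipeline computes the published numbers from
sequences with the published architecture, not that the deposited
residues round-trip.

## Numerical and degenerate-input conventions

- Longest-ORF ties break by + strand before −, then earliest
  forward-strand start, then frame number. ORFs running off the contig
  (no stop) are flagged but eligible.
- Incomplete terminal codons are dropped, never padded.
- Transcript records whose longest ORF is shorter than `min_orf_aa`
  (default 60 — shorter than any known neuropeptide precursor) are
  skipped in transcript mode.
- Signal prediction requires ≥30 residues; shorter proteins are
  annotated without a signal (pipeline) or raise (direct call).
- Consensus motifs stop before the first position at which any peptide
  is exhausted and strip leading wildcards; peptide sets sharing no
  C-terminal residue have no consensus and raise.
- Empty FASTA inputs produce empty reports with a warning, exit code 0.

## Problem sizes

Test-suite and acceptance-script simulations use 125 noise-free
precursors (5 replicates × 25) for recovery, 200 decoys for the
false-positive rate, 5 replicate 51-transcript scans for retrieval, and
a 5-point substitution sweep at 30 precursors — sizes at which the
binomial uncertainty on the reported rates is already far below the
asserted margins, while the whole suite runs in well under a minute.
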