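import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from salm.annotate import annotate_precursor
from salm.compare import (
    ScoringScheme,
    StructureSignature,
    align_precursors,
    classify_gene_structure,
    global_align,
    local_align,
    map_peptide_positions,
    scan_transcriptome,
)
from salm.motif import Category
from salm.peptides import S1
from salm.seqio import GeneModel, SequenceRecord
from salm.synth import SyntheticSpec, generate_transcriptome, reverse_translate
from salm.synthetic_standins import (
    build_standin,
    StandinSpec,
    gene_model_standins,
    mirror_gene_model,
    standin_precursor,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _reference_aligner(mode: str) -> Align.PairwiseAligner:
    """Independent dynamic-programming oracle (Biopython)."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = mode
    return aligner


def test_self_match_score_is_sum_of_diagonal_entries():
    scheme = ScoringScheme(min_report_score=1)
    target = "DDD" + S1 + "EEE"
    aln = local_align(S1, target, scheme)
    assert aln.score == scheme.self_score(S1)
    assert aln.identity == 1.0
    assert target[aln.target_span[0] : aln.target_span[1]] == S1


def test_low_scoring_alignment_reported_absent():
    scheme = ScoringScheme(min_report_score=25)
    assert local_align("WWWWW", "AAAAAAAA", scheme) is None


def test_alignment_scores_match_independent_dp_oracle():
    """100 random short-query instances against both SW and NW oracles."""
    rng = np.random.default_rng(11)
    loc, glo = _reference_aligner("local"), _reference_aligner("global")
    scheme = ScoringScheme(min_report_score=-(10**6))
    for _ in range(100):
        q = "".join(rng.choice(AA, size=int(rng.integers(5, 16))))
        t = "".join(rng.choice(AA, size=int(rng.integers(20, 201))))
        mine = local_align(q, t, scheme)
        ref = loc.score(q, t)
        got = mine.score if mine else 0
        if ref > 0:
            assert got == ref
        assert global_align(q, t, scheme).score == glo.score(q, t)


def test_traceback_identity_consistent_with_columns():
    scheme = ScoringScheme(min_report_score=1)
    aln = global_align("GFNSALMF", "GFNSGLMF", scheme)
    matches = sum(
        1 for a, b in zip(aln.aligned_query, aln.aligned_target) if a == b and a != "-"
    )
    assert aln.identity == matches / aln.n_columns


def test_scheme_validation():
    with pytest.raises(ValueError):
        ScoringScheme(gap_open=-1, gap_extend=-11)


def test_scan_finds_planted_transcript(small_transcriptome):
    records, truths = small_transcriptome
    pep = truths[0].peptides[0].sequence
    query = SequenceRecord(id="q", seq=pep, alphabet_kind="protein")
    hits = scan_transcriptome([query], records)
    assert hits and hits[0].target_id == truths[0].transcript_id


def test_scan_s1_query_against_planted_s1_precursor():
    rng = np.random.default_rng(7)
    prec = standin_precursor("Pmin-L-prec")  # contains S1
    tx = reverse_translate(prec.seq, rng, utr_len=(50, 120))
    records = [SequenceRecord(id="planted", seq=tx, alphabet_kind="nucleotide")]
    for i in range(50):
        shuffled = "".join(np.asarray(list(tx))[rng.permutation(len(tx))])
        records.append(
            SequenceRecord(id=f"decoy{i}", seq=shuffled, alphabet_kind="nucleotide")
        )
    query = SequenceRecord(id="S1", seq=S1, alphabet_kind="protein")
    hits = scan_transcriptome([query], records)
    assert hits[0].target_id == "planted"


def test_scan_empty_transcript_list():
    q = SequenceRecord(id="q", seq=S1, alphabet_kind="protein")
    assert scan_transcriptome([q], []) == []


def test_scan_rejects_long_queries():
    q = SequenceRecord(id="q", seq="A" * 31, alphabet_kind="protein")
    with pytest.raises(ValueError):
        scan_transcriptome([q], [])


def test_hit_count_monotone_in_threshold(small_transcriptome):
    records, truths = small_transcriptome
    pep = truths[0].peptides[0].sequence
    query = SequenceRecord(id="q", seq=pep, alphabet_kind="protein")
    self_score = ScoringScheme().self_score(pep)
    counts = []
    for frac in (1.0, 0.8, 0.6, 0.4, 0.2):
        scheme = ScoringScheme(min_report_score=int(frac * self_score))
        counts.append(len(scan_transcriptome([query], records, scheme)))
    assert counts == sorted(counts)


def test_precursor_self_alignment_identity_one():
    ann = annotate_precursor(standin_precursor("Ovic-L-prec"))
    aln = align_precursors(ann, ann)
    assert aln.identity == 1.0


def test_mutated_duplicate_retains_high_identity(rng):
    prec = standin_precursor("Pmin-L-prec")
    seq = list(prec.seq)
    n_sub = int(0.05 * len(seq))
    for pos in rng.choice(len(seq), size=n_sub, replace=False):
        choices = [a for a in AA if a != seq[pos]]
        seq[pos] = choices[int(rng.integers(len(choices)))]
    mutated = SequenceRecord(id="dup", seq="".join(seq), alphabet_kind="protein")
    aln = align_precursors(annotate_precursor(prec), annotate_precursor(mutated))
    assert aln.identity >= 0.90


def _oangulata_standin():
    """Four-peptide L-type precursor with SAMLLamide at ordinal 3."""
    return build_standin(
        StandinSpec(
            record_id="Oang-L-prec",
            signal_len=20,
            peptides=(
                ("AGLDQLNSGLAF", "KR"),
                ("SRLPFHSGLMQ", "KR"),
                ("ADSPDSAMLL", "KR"),  # LxL category
                ("ADQNPGTDASGMTF", "KR"),
            ),
            total_len=170,
        )
    )


def test_ordinal_mapping_flags_category_divergence():
    a = annotate_precursor(standin_precursor("Ovic-L-prec"))
    b = annotate_precursor(_oangulata_standin())
    pairs = map_peptide_positions(a, b)
    assert len(pairs) == 4
    third = pairs[2]
    assert third.peptide_a.category.category is Category.FXL_TYPE  # TGFMMamide
    assert third.peptide_b.category.category is Category.LXL_TYPE  # SAMLLamide
    assert not third.same_category
    assert pairs[0].same_category and pairs[3].same_category


def test_ordinal_mapping_self_and_unpaired():
    ann = annotate_precursor(standin_precursor("Ovic-L-prec"))
    assert all(p.same_category for p in map_peptide_positions(ann, ann))
    shorter = build_standin(
        StandinSpec(
            record_id="short",
            signal_len=20,
            peptides=(("AGLDQLNSGLTF", "KR"), ("ADSPDATGFMM", "KR")),
            total_len=120,
        )
    )
    pairs = map_peptide_positions(ann, annotate_precursor(shorter))
    assert pairs[-1].peptide_b is None and not pairs[-1].same_category


def test_gene_structure_signatures_match_published_layouts():
    models = gene_model_standins()
    expected = {
        "Pmin-L-gene": StructureSignature.L_SIGNATURE,
        "Pmin-F-gene": StructureSignature.F_SIGNATURE,
        "Spur-L-gene": StructureSignature.L_SIGNATURE,
        "Spur-F-gene": StructureSignature.F_SIGNATURE,
    }
    for name, model in models.items():
        assert classify_gene_structure(model) is expected[name]
        # strand flip with coordinate mirroring leaves the call unchanged
        assert classify_gene_structure(mirror_gene_model(model)) is expected[name]


def test_single_exon_gene_undetermined_when_cds_at_boundary():
    model = GeneModel(gene_id="g", strand="+", exons=((0, 900),), cds=(0, 600))
    assert classify_gene_structure(model) is StructureSignature.UNDETERMINED
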