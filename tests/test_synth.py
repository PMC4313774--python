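import numpy as np
import pytest

from salm.annotate import annotate_precursor
from salm.motif import classify_sequence
from salm.orf import longest_orf_protein, six_frame_translate
from salm.pipeline import annotate_records, is_putative_precursor
from salm.seqio import SequenceRecord
from salm.synth import (
    SyntheticSpec,
    generate_precursor,
    generate_transcriptome,
    reverse_translate,
    truth_to_tsv,
)


def test_spec_validation():
    with pytest.raises(ValueError):
        SyntheticSpec(category_mix=(0.5, 0.5, 0.0, 0.0, 0.5))
    with pytest.raises(ValueError):
        SyntheticSpec(substitution_rate=1.0)
    with pytest.raises(ValueError):
        SyntheticSpec(peptides_per_precursor=(5, 3))


def test_zero_peptide_precursor():
    rng = np.random.default_rng(0)
    protein, truth = generate_precursor(
        SyntheticSpec(peptides_per_precursor=(0, 0)), rng
    )
    assert truth.peptides == ()
    assert protein.startswith("M")


def test_identical_seed_gives_identical_output():
    spec = SyntheticSpec(n_precursors=3, n_decoys=5, seed=123)
    r1, t1 = generate_transcriptome(spec)
    r2, t2 = generate_transcriptome(spec)
    assert [(r.id, r.seq) for r in r1] == [(r.id, r.seq) for r in r2]
    assert truth_to_tsv(t1) == truth_to_tsv(t2)


def test_planted_categories_consistent_with_classifier():
    spec = SyntheticSpec(
        n_precursors=10, n_decoys=0, category_mix=(0.3, 0.3, 0.15, 0.15, 0.1), seed=5
    )
    _, truths = generate_transcriptome(spec)
    n = 0
    for t in truths:
        for p in t.peptides:
            assert classify_sequence(p.sequence, p.amidated).category is p.category
            n += 1
    assert n > 0


def test_transcript_count(small_transcriptome):
    records, truths = small_transcriptome
    assert len(records) == 51
    assert len(truths) == 1


def test_reverse_translate_round_trip():
    rng = np.random.default_rng(3)
    protein = "MKLLVAGFNSALMF"
    nt = reverse_translate(protein, rng, utr_len=(20, 60))
    assert longest_orf_protein(nt) == protein
    assert any(protein in frame for frame in six_frame_translate(nt).values())


def test_reverse_translate_empty_utrs_length():
    rng = np.random.default_rng(4)
    protein = "MK"
    nt = reverse_translate(protein, rng, utr_len=(0, 0))
    assert len(nt) == 3 * (len(protein) + 1)  # codons + stop


def test_noise_free_pipeline_recovery_is_total():
    spec = SyntheticSpec(n_precursors=20, n_decoys=0, seed=11)
    records, truths = generate_transcriptome(spec)
    anns = {a.record.id: a for a in annotate_records(records, mode="transcript")}
    for t in truths:
        ann = anns[t.transcript_id]
        got = {(p.sequence, p.span, p.category.category) for p in ann.peptides}
        want = {(p.sequence, p.span, p.category) for p in t.peptides}
        assert got == want


def test_decoys_rarely_pass_for_precursors():
    """Shuffled-composition decoys: ≤2% may present a classifiable peptide."""
    n_decoys = fp = 0
    for seed in (1, 2, 3, 4, 5):
        spec = SyntheticSpec(n_precursors=25, n_decoys=40, seed=seed)
        records, _ = generate_transcriptome(spec)
        decoys = [r for r in records if r.id.startswith("decoy")]
        n_decoys += len(decoys)
        for ann in annotate_records(decoys, mode="transcript"):
            fp += is_putative_precursor(ann)
    assert n_decoys == 200
    assert fp / n_decoys <= 0.02


def test_recovery_non_increasing_under_noise():
    rates = [0.0, 0.025, 0.05, 0.075, 0.1]
    recovery = []
    for rate in rates:
        spec = SyntheticSpec(n_precursors=30, n_decoys=0, substitution_rate=rate, seed=99)
        records, truths = generate_transcriptome(spec)
        anns = {a.record.id: a for a in annotate_records(records, mode="transcript")}
        total = found = 0
        for t in truths:
            want = {(p.sequence, p.span, p.category) for p in t.peptides}
            ann = anns.get(t.transcript_id)
            got = (
                {(p.sequence, p.span, p.category.category) for p in ann.peptides}
                if ann
                else set()
            )
            total += len(want)
            found += len(want & got)
        recovery.append(found / total)
    assert recovery[0] == 1.0
    assert all(a >= b for a, b in zip(recovery, recovery[1:]))
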