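import numpy as np
import pytest

from salm.annotate import (
    AnnotationConfig,
    CleavageSite,
    annotate_precursor,
    extract_peptides,
    find_cleavage_sites,
    predict_signal_peptide,
)
from salm.motif import Category
from salm.seqio import SequenceRecord
from salm.synth import SyntheticSpec, generate_precursor


def test_signal_peptide_absent_without_hydrophobic_core():
    assert predict_signal_peptide("M" + "D" * 40) is None


def test_signal_peptide_requires_min_length():
    with pytest.raises(ValueError):
        predict_signal_peptide("MLLLLLLLLLALA")


def test_signal_recovered_on_planted_precursor():
    rng = np.random.default_rng(42)
    spec = SyntheticSpec(signal_len=(18, 18), seed=42)
    protein, truth = generate_precursor(spec, rng)
    sp = predict_signal_peptide(protein)
    assert sp is not None and sp.span == (0, 18) == truth.signal_span


def test_dibasic_sites_simple_and_greedy():
    protein = "M" * 20 + "AGKRSS"
    sites = find_cleavage_sites(protein, signal_end=20)
    assert [(s.pos, s.kind) for s in sites] == [(22, "KR")]
    # overlapping run KRRK parses greedily left-to-right: KR then RK
    run = "A" * 10 + "KRRK" + "A" * 5
    sites = find_cleavage_sites(run, signal_end=0)
    assert [(s.pos - 10, s.kind) for s in sites] == [(0, "KR"), (2, "RK")]


def _sig(end):
    from salm.annotate import SignalPeptide

    return SignalPeptide(span=(0, end), score=0.0)


def test_extract_simple_amidated_peptide():
    # signal + GFNSALMF + G + KR + spacer
    protein = "M" + "L" * 16 + "ALA" + "GFNSALMFG" + "KR" + "DDEEDD"
    sites = find_cleavage_sites(protein, 20)
    peptides, _ = extract_peptides(protein, _sig(20), sites)
    assert len(peptides) == 1
    p = peptides[0]
    assert p.sequence == "GFNSALMF" and p.amidated
    assert p.span == (20, 28)
    assert p.category.category is Category.L_TYPE


def test_non_amidated_candidate_dropped_when_required():
    protein = "M" + "L" * 16 + "ALA" + "AAAAA" + "KR" + "DDEEDD"
    sites = find_cleavage_sites(protein, 20)
    with_req, _ = extract_peptides(protein, _sig(20), sites, require_amidation=True)
    without, _ = extract_peptides(protein, _sig(20), sites, require_amidation=False)
    assert with_req == []
    assert [p.sequence for p in without] == ["AAAAA", "DDEEDD"]


def test_monobasic_rescue_splits_classifiable_peptides():
    # peptide1 G K spacer KR peptide2 G KR : K is honored because
    # GFNSALMF is amidated and classifiable
    protein = "M" + "L" * 16 + "ALA" + "GFNSALMFG" + "K" + "DDEDDE" + "KR" + "SGYSVLYFG" + "KR" + "DDD"
    sites = find_cleavage_sites(protein, 20)
    peptides, all_sites = extract_peptides(protein, _sig(20), sites)
    assert [p.sequence for p in peptides] == ["GFNSALMF", "SGYSVLYF"]
    assert any(s.kind == "mono_K" for s in all_sites)


def test_monobasic_not_honored_for_unclassifiable_peptide():
    # DDDDDG is amidated but ATYPICAL → the K is not a cleavage site
    protein = "M" + "L" * 16 + "ALA" + "DDDDDG" + "K" + "EEEEEE"
    sites = find_cleavage_sites(protein, 20)
    peptides, all_sites = extract_peptides(protein, _sig(20), sites)
    assert peptides == []
    assert all(s.width == 2 for s in all_sites)


def _dibasic_only_oracle(protein, start, sites, min_len=5):
    """Independent pass-1 emulation: cut at dibasic sites only, strip
    stray boundary K/R, keep G-terminated candidates of min length."""
    bounds = [start]
    for s in sorted(sites, key=lambda s: s.pos):
        bounds.extend((s.pos, s.end))
    bounds.append(len(protein))
    out = []
    for i in range(0, len(bounds), 2):
        seg_start, seg_end = bounds[i], bounds[i + 1]
        seq = protein[seg_start:seg_end]
        while seq and seq[0] in "KR":
            seq, seg_start = seq[1:], seg_start + 1
        while seq and seq[-1] in "KR":
            seq = seq[:-1]
        if seq.endswith("G") and len(seq) - 1 >= min_len:
            out.append((seq[:-1], (seg_start, seg_start + len(seq) - 1)))
    return out


def test_monobasic_rescue_is_monotone_augmentation():
    rng = np.random.default_rng(7)
    spec = SyntheticSpec(dibasic_fraction=0.5, peptides_per_precursor=(4, 8), seed=7)
    for _ in range(25):
        protein, _ = generate_precursor(spec, rng)
        sites = find_cleavage_sites(protein, 45)
        full, _ = extract_peptides(protein, _sig(45), sites)
        got = {(p.sequence, p.span) for p in full}
        pass1 = set(_dibasic_only_oracle(protein, 45, sites))
        assert pass1 <= got


def test_planted_peptides_recovered_exactly():
    rng = np.random.default_rng(42)
    spec = SyntheticSpec(peptides_per_precursor=(6, 6), seed=42)
    protein, truth = generate_precursor(spec, rng)
    rec = SequenceRecord(id="p", seq=protein, alphabet_kind="protein")
    ann = annotate_precursor(rec)
    assert len(ann.peptides) == 6
    for got, want in zip(ann.peptides, truth.peptides):
        assert got.sequence == want.sequence
        assert got.span == want.span
        assert got.amidated
        assert got.category.category is want.category


def test_annotation_invariants_across_seeds():
    rng = np.random.default_rng(0)
    spec = SyntheticSpec(dibasic_fraction=0.7, seed=0)
    for _ in range(30):
        protein, _ = generate_precursor(spec, rng)
        ann = annotate_precursor(
            SequenceRecord(id="p", seq=protein, alphabet_kind="protein")
        )
        # spans disjoint, sorted, after the signal
        spans = [p.span for p in ann.peptides]
        assert spans == sorted(spans)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        assert all(s >= ann.signal.end for s, _ in spans)
        # composition conserved
        assert sum(ann.composition.values()) == len(ann.peptides)
        # ordinals are 1..n
        assert [p.ordinal for p in ann.peptides] == list(range(1, len(spans) + 1))


def test_signal_override_pins_published_cleavage():
    protein = "M" + "L" * 25 + "ALA" + "GFNSALMFG" + "KR" + "DDEEDD"
    rec = SequenceRecord(id="px", seq=protein, alphabet_kind="protein")
    cfg = AnnotationConfig(signal_overrides={"px": 22})
    ann = annotate_precursor(rec, cfg)
    assert ann.signal.span == (0, 22)


def test_precursor_with_no_peptides():
    protein = "M" + "L" * 16 + "ALA" + "DDEEDDEEDDEE"
    ann = annotate_precursor(SequenceRecord(id="p", seq=protein, alphabet_kind="protein"))
    assert ann.peptides == []
    assert sum(ann.composition.values()) == 0
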