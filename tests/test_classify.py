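"""Classifier tests, including a brute-force alignment oracle.

The oracle is an independent Smith-Waterman-Gotoh implemented as plain
dynamic programming over explicit match/gap states; it checks the
optimal local score produced by the production aligner on short
sequences.
"""

import random

import pytest
from Bio.Align import substitution_matrices

from histevo.classify import (
    ClassifierConfig,
    FoldAlignmentResult,
    _aligner,
    align_to_fold,
    deduplicate,
    filter_variants,
    global_similarity,
    is_canonical_hit,
    select_canonical_per_species,
)
from histevo.sequence_io import AMINO_ACIDS, HistoneSequence

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_gotoh_score(a: str, b: str, gap_open: float = 11.0,
                   gap_extend: float = 1.0) -> float:
    """Brute-force local alignment score (first gap residue costs
    gap_open, each further residue gap_extend)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open, F[i - 1][j] - gap_extend)
            s = BLOSUM62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestAlignToFold:
    def test_self_alignment_is_perfect(self, h2a_ref):
        r = align_to_fold(h2a_ref.human_fold, h2a_ref.human_fold)
        assert r.identity == 1.0 and r.overlap == 1.0
        assert r.fold_span_on_candidate == (1, len(h2a_ref.human_fold))

    def test_single_substitution_identity(self, h2a_ref):
        fold = h2a_ref.human_fold
        L = len(fold)
        mutated = fold[:10] + ("A" if fold[10] != "A" else "G") + fold[11:]
        r = align_to_fold(mutated, fold)
        assert r.identity == pytest.approx((L - 1) / L)
        assert r.overlap == 1.0

    def test_half_fold_overlap(self, h2a_ref):
        fold = h2a_ref.human_fold
        half = fold[: len(fold) // 2]
        r = align_to_fold(half, fold)
        assert r.overlap == pytest.approx(len(half) / len(fold))
        assert r.identity == 1.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_to_fold("SGRGK", "")

    def test_scores_match_brute_force_dp(self, classifier_config):
        rng = random.Random(42)
        aligner = _aligner("local", classifier_config)
        for _ in range(40):
            a = "".join(rng.choices(AMINO_ACIDS, k=rng.randint(5, 30)))
            b = "".join(rng.choices(AMINO_ACIDS, k=rng.randint(5, 30)))
            assert aligner.score(a, b) == pytest.approx(sw_gotoh_score(a, b))


class TestThresholds:
    @pytest.mark.parametrize("identity,overlap,expected", [
        (1.0, 1.0, True),
        (0.35, 0.95, False),   # strict: exactly 35% identity fails
        (0.80, 0.90, False),   # strict: exactly 90% overlap fails
        (0.351, 0.901, True),
        (0.36, 0.89, False),
    ])
    def test_strict_inequalities(self, identity, overlap, expected):
        r = FoldAlignmentResult("x", "H2A", identity, overlap, (1, 10), 10)
        assert is_canonical_hit(r) is expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ClassifierConfig(identity_threshold=1.5)


class TestDeduplicate:
    def test_same_species_duplicates_collapse(self):
        a = HistoneSequence("a", "sp1", "H2A", "SGRGKAAAKA")
        b = HistoneSequence("b", "sp1", "H2A", "SGRGKAAAKA")
        kept = deduplicate([a, b])
        assert [r.seq_id for r in kept] == ["a"]
        assert "duplicate" in b.flags and "duplicate" not in a.flags

    def test_cross_species_identical_sequences_retained(self):
        a = HistoneSequence("a", "sp1", "H2A", "SGRGKAAAKA")
        b = HistoneSequence("b", "sp2", "H2A", "SGRGKAAAKA")
        assert len(deduplicate([a, b])) == 2

    def test_all_unique_identity(self):
        recs = [HistoneSequence(f"s{i}", "sp1", "H2A", "SGRGK" + aa)
                for i, aa in enumerate("AC")]
        assert deduplicate(recs) == recs


class TestVariantFilter:
    def test_canonical_human_is_retained(self, reference_set, h2a_ref):
        rec = HistoneSequence("hs", "hsapiens", "H2A", h2a_ref.human)
        assert filter_variants([rec], reference_set) == [rec]
        assert "variant" not in rec.flags

    def test_acidic_tail_decoy_flagged(self, reference_set, h2a_ref):
        tail = "EDEEDSEDEEGDESDGEKDEDSEEDGEDEESEDDEGSEDE"
        decoy = HistoneSequence("dec", "hsapiens", "H2A", h2a_ref.human + tail)
        out = filter_variants([decoy], reference_set)
        assert out == [] and "variant" in decoy.flags

    def test_decoy_scoring_by_brute_force(self, reference_set, h2a_ref):
        # independent check of the strictly-closer decision on this pair
        tail = "EDEEDSEDEEGDESDGEKDEDSEEDGEDEESEDDEGSEDE"
        decoy = h2a_ref.human + tail
        macro = reference_set["H2A"].variants["macroh2a_like"]
        assert global_similarity(decoy, macro) > global_similarity(
            decoy, h2a_ref.human)


class TestCanonicalSelection:
    def test_identical_to_reference_wins(self, reference_set, h2a_ref):
        exact = HistoneSequence("exact", "sp1", "H2A", h2a_ref.human)
        near = h2a_ref.human[:-3] + "AAA"
        other = HistoneSequence("other", "sp1", "H2A", near)
        sel = select_canonical_per_species([exact, other], reference_set)
        assert sel[("sp1", "H2A")] is exact
        assert "canonical" in exact.flags

    def test_tie_breaks_deterministic(self, reference_set, h2a_ref):
        # same residues, different ids: lexicographically smaller id wins
        a = HistoneSequence("zzz", "sp1", "H2A", h2a_ref.human)
        b = HistoneSequence("aaa", "sp1", "H2A", h2a_ref.human)
        sel = select_canonical_per_species([a, b], reference_set)
        assert sel[("sp1", "H2A")] is b

    def test_at_most_one_per_species(self, reference_set, h2a_ref):
        recs = [HistoneSequence(f"s{i}", f"sp{i % 3}", "H2A", h2a_ref.human)
                for i in range(9)]
        sel = select_canonical_per_species(recs, reference_set)
        assert len(sel) == 3

    def test_flagged_records_excluded(self, reference_set, h2a_ref):
        a = HistoneSequence("a", "sp1", "H2A", h2a_ref.human, flags={"variant"})
        sel = select_canonical_per_species([a], reference_set)
        assert sel == {}


class TestPackagedReferencesSelfConsistent:
    @pytest.mark.parametrize("family", ["H2A", "H2B", "H3", "H4"])
    def test_canonicals_pass_own_fold(self, reference_set, family):
        ref = reference_set[family]
        for seq, fold in ((ref.human, ref.human_fold),
                          (ref.yeast, ref.yeast_fold)):
            r = align_to_fold(seq, fold)
            assert r.identity == 1.0 and r.overlap == 1.0
            assert is_canonical_hit(r)
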