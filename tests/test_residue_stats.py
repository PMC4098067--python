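import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from histevo.domains import partition_domains
from histevo.residue_stats import (
    compare_size_classes,
    composition_table,
    mann_whitney_u,
    residue_counts,
    residue_presence_genome_test,
    violin_summary,
)
from histevo.sequence_io import AMINO_ACIDS, SpeciesRecord


def enumeration_two_sided_p(a, b):
    """Independent oracle: full enumeration of tie-free rank assignments."""
    n, m = len(a), len(b)
    pooled = sorted(a + b)
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(rank[x] for x in a) - n * (n + 1) / 2
    us = [sum(c) - n * (n + 1) / 2
          for c in itertools.combinations(range(1, n + m + 1), n)]
    p_less = sum(u <= u_obs for u in us) / len(us)
    p_greater = sum(u >= u_obs for u in us) / len(us)
    return u_obs, min(1.0, 2.0 * min(p_less, p_greater))


class TestResidueCounts:
    def test_human_printed_ntd_has_four_arginines(self):
        counts = residue_counts("SGRGKQGGKTRAKAKSRSSRAG")
        assert counts["R"] == 4
        assert counts["S"] + counts["T"] == 5

    def test_yeast_printed_ntd_has_one_arginine(self, yeast_partition):
        assert residue_counts(yeast_partition.ntd)["R"] == 1

    def test_empty_string_all_zero(self):
        assert set(residue_counts("").values()) == {0}

    def test_counts_sum_to_domain_length(self, human_partition):
        table = composition_table([human_partition])
        for _, row in table.iterrows():
            assert sum(row[aa] for aa in AMINO_ACIDS) == row["length"]


class TestMannWhitney:
    def test_textbook_separated_example(self):
        r = mann_whitney_u([1, 2], [3, 4])
        assert r.U == 0
        assert r.p_two_sided == pytest.approx(2 / 6)
        assert r.method == "exact"

    def test_identical_samples_p_one(self):
        r = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.U == pytest.approx(9 / 2)
        assert r.p_two_sided == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_enumeration_full_sweep(self):
        # complete sweep over every tie-free rank configuration, n,m <= 4
        for n in range(1, 5):
            for m in range(1, 5):
                total = n + m
                for a_ranks in itertools.combinations(range(1, total + 1), n):
                    a = [float(r) for r in a_ranks]
                    b = [float(r) for r in range(1, total + 1)
                         if r not in a_ranks]
                    res = mann_whitney_u(a, b)
                    u_oracle, p_oracle = enumeration_two_sided_p(a, b)
                    assert res.method == "exact"
                    assert res.U == pytest.approx(u_oracle)
                    assert res.p_two_sided == pytest.approx(p_oracle)

    def test_normal_approx_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.integers(0, 6, 25).tolist()
            b = rng.integers(0, 7, 35).tolist()
            res = mann_whitney_u(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
            assert res.method == "normal_approx"
            assert res.U == pytest.approx(float(ref.statistic))
            assert res.p_two_sided == pytest.approx(float(ref.pvalue))

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 100), min_size=1, max_size=8),
           st.lists(st.integers(0, 100), min_size=1, max_size=8))
    def test_u_statistics_sum_to_nanb(self, a, b):
        ra = mann_whitney_u(a, b)
        rb = mann_whitney_u(b, a)
        assert ra.U + rb.U == pytest.approx(len(a) * len(b))

    def test_monotone_shift_never_helps_shifted_sample(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 1, 12).tolist()
        b = rng.normal(0, 1, 12).tolist()

        def one_sided_b_larger(bb):
            # U of a small <=> b stochastically larger
            r = mann_whitney_u(a, bb)
            return r.U

        u0 = one_sided_b_larger(b)
        for shift in (0.5, 1.0, 5.0):
            u = one_sided_b_larger([x + shift for x in b])
            assert u <= u0
            u0 = u


def _cohort(counts_small, counts_large):
    species, parts = [], []
    i = 0
    for g, counts in ((50.0, counts_small), (2000.0, counts_large)):
        for c in counts:
            sid = f"sp{i:03d}"
            species.append(SpeciesRecord(sid, "fungi", g))
            ntd = "R" * int(c) + "A" * (8 - int(c))
            seq = ntd + "LTFPVGRV"
            parts.append(partition_domains(seq, (9, len(seq)),
                                           species_id=sid, seq_id=sid))
            i += 1
    return species, composition_table(parts)


class TestCompareSizeClasses:
    def test_fully_separated_groups_tiny_p(self):
        # every large species has one more NTD arginine than every small one
        species, table = _cohort([2] * 20, [3] * 20)
        # constant-within-group counts are maximally tied -> approx path
        c = compare_size_classes(table, species, ("R",))
        assert c.p_two_sided < 0.001
        assert (c.n_a, c.n_b) == (20, 20)

    def test_identical_distributions_p_one(self):
        species, table = _cohort([1, 2, 3, 4], [1, 2, 3, 4])
        c = compare_size_classes(table, species, ("R",))
        assert c.p_two_sided == 1.0

    def test_small_group_rejected(self):
        species, table = _cohort([2], [3, 3])
        with pytest.raises(ValueError, match="small"):
            compare_size_classes(table, species, ("R",))


class TestResidueSweep:
    def test_sweep_covers_alphabet_and_flags_programmed_residue(self):
        from histevo.residue_stats import residue_sweep
        species, table = _cohort([1, 1, 2, 2, 1], [3, 3, 4, 4, 3])
        df = residue_sweep(table, species, bonferroni=True)
        assert len(df) == 20
        r_row = df[df["residue"] == "R"].iloc[0]
        assert r_row["p_two_sided"] < 0.05
        assert r_row["p_adjusted"] == pytest.approx(
            min(1.0, r_row["p_two_sided"] * 20))
        # untouched residues carry no signal
        assert df[df["residue"] == "W"]["p_two_sided"].iloc[0] == 1.0


class TestPresenceGenomeTest:
    def test_fully_separated_presence_groups(self):
        species = [SpeciesRecord(f"a{i}", "fungi", 10.0 + i) for i in range(10)]
        species += [SpeciesRecord(f"b{i}", "plants", 2000.0 + i)
                    for i in range(10)]
        presence = {s.species_id: s.genome_size_mbp > 1000 for s in species}
        r = residue_presence_genome_test(species, presence)
        assert r.p_two_sided < 0.01
        assert r.method == "exact" or r.p_two_sided < 0.01

    def test_permuted_labels_uniform_p(self):
        # under a permutation null the p-value should not concentrate low
        rng = np.random.default_rng(11)
        species = [SpeciesRecord(f"s{i}", "fungi", float(g))
                   for i, g in enumerate(rng.uniform(8, 5600, 24))]
        ps = []
        for _ in range(200):
            flags = rng.permutation([True] * 12 + [False] * 12)
            presence = {s.species_id: bool(f)
                        for s, f in zip(species, flags)}
            ps.append(residue_presence_genome_test(species, presence).p_two_sided)
        assert np.mean(np.array(ps) < 0.05) < 0.12

    def test_single_member_group_rejected(self):
        species = [SpeciesRecord("a", "fungi", 10.0),
                   SpeciesRecord("b", "fungi", 20.0)]
        with pytest.raises(ValueError):
            residue_presence_genome_test(species, {"a": True, "b": True})


class TestViolinSummary:
    def test_constant_class(self):
        df = violin_summary({"small": [4, 4, 4]})
        row = df.iloc[0]
        assert row["median"] == 4 and row["frequencies"] == {4: 3}

    def test_empty_class(self):
        df = violin_summary({"large": []})
        assert df.iloc[0]["n"] == 0

    def test_mixed_counts_median(self):
        df = violin_summary({"medium": [0, 1, 1, 2]})
        assert df.iloc[0]["median"] == 1
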