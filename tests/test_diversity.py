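import numpy as np
import pytest

from conftest import make_gm
from coalpop.datatypes import HaplotypeTable, SequenceAlignment
from coalpop.diversity import (
    combine_across_loci,
    haplotype_diversity,
    hwe_probability_test,
    linkage_disequilibrium_test,
    locus_summaries,
    mean_pairwise_differences,
)
from coalpop.synth import msat_locus_equilibrium, pair_copies_to_genotypes
from oracles import naive_haplotype_diversity, naive_pairwise_diffs


def _ht(counts):
    seqs = [f"H{i}" for i in range(len(counts))]
    return HaplotypeTable(
        haplotype_sequences=seqs,
        counts=np.array(counts).reshape(-1, 1),
        populations=["p"],
    )


class TestHaplotypeDiversity:
    @pytest.mark.parametrize(
        "counts,expected",
        [([2], 0.0), ([1, 1], 1.0), ([3, 1], 0.5)],
    )
    def test_hand_cases(self, counts, expected):
        hd, sd = haplotype_diversity(_ht(counts), "p")
        assert hd == pytest.approx(expected)
        assert sd >= 0

    def test_matches_naive_formula(self):
        counts = [7, 5, 3, 1, 1]
        hd, _ = haplotype_diversity(_ht(counts), "p")
        assert hd == pytest.approx(naive_haplotype_diversity(counts), rel=1e-12)

    def test_relabeling_invariance(self):
        a, _ = haplotype_diversity(_ht([5, 3, 2]), "p")
        b, _ = haplotype_diversity(_ht([2, 5, 3]), "p")
        assert a == pytest.approx(b)

    def test_n_below_two_errors(self):
        with pytest.raises(ValueError):
            haplotype_diversity(_ht([1]), "p")


class TestMeanPairwiseDifferences:
    def test_hand_enumeration(self, tiny_alignment):
        k, sd = mean_pairwise_differences(tiny_alignment)
        assert k == pytest.approx(7 / 6)

    def test_identical_sequences_zero(self):
        aln = SequenceAlignment(["a", "b"], ["ACGT", "ACGT"])
        assert mean_pairwise_differences(aln)[0] == 0.0

    def test_fully_different_pair(self):
        aln = SequenceAlignment(["a", "b"], ["AAAA", "TTTT"])
        assert mean_pairwise_differences(aln)[0] == pytest.approx(4.0)

    def test_matches_naive_on_fixture(self, ashw):
        aln, _, _ = ashw
        k, _ = mean_pairwise_differences(aln)
        assert k == pytest.approx(naive_pairwise_diffs(aln.sequences), rel=1e-12)


class TestLocusSummaries:
    def test_monomorphic(self):
        gm = make_gm([[(1, 1)], [(1, 1)]])
        row = locus_summaries(gm).loc["L0"]
        assert row["K"] == 1 and row["Ho"] == 0 and row["He"] == 0

    def test_all_heterozygous(self):
        gm = make_gm([[(1, 2)], [(1, 2)]])
        row = locus_summaries(gm).loc["L0"]
        assert row["K"] == 2 and row["Ho"] == 1.0
        assert row["He"] == pytest.approx(2 / 3)

    def test_ho_close_to_he_under_hwe(self):
        rng = np.random.default_rng(3)
        sizes = msat_locus_equilibrium(4000, 2.0, 0.9, 3.5, rng)
        rng.shuffle(sizes)  # random union of gametes
        gm = pair_copies_to_genotypes([sizes])
        row = locus_summaries(gm).loc["L01"]
        assert row["Ho"] == pytest.approx(row["He"], abs=0.03)


class TestHWEProbabilityTest:
    def test_monomorphic_degenerate(self):
        gm = make_gm([[(1, 1)], [(1, 1)]])
        tr = hwe_probability_test(gm, "L0")
        assert tr.p_value == 1.0 and "degenerate" in tr.flags

    def test_two_individuals_exact_enumeration(self):
        """n=2, alleles 2A/2B, both heterozygous: two possible arrays with
        conditional probabilities 2/3 (both het) and 1/3 (both hom); the
        observed array is the more probable one, so p = 1."""
        gm = make_gm([[(1, 2)], [(1, 2)]])
        tr = hwe_probability_test(gm, "L0")
        assert tr.method == "exact"
        assert tr.p_value == pytest.approx(1.0)

    def test_exact_detects_extreme_het_deficit(self):
        rows = [[(1, 1)]] * 12 + [[(2, 2)]] * 12
        gm = make_gm(rows)
        tr = hwe_probability_test(gm, "L0")
        assert tr.p_value < 1e-4

    def test_mc_path_multiallelic_extreme(self):
        # three alleles, all homozygotes: strong HWE departure
        rows = [[(1, 1)]] * 8 + [[(2, 2)]] * 8 + [[(3, 3)]] * 8
        gm = make_gm(rows)
        tr = hwe_probability_test(gm, "L0", reps=2000, seed=1)
        assert tr.method == "permutation"
        assert tr.p_value < 0.01


class TestLinkageDisequilibriumTest:
    def test_duplicated_locus_maximal_association(self):
        rng = np.random.default_rng(5)
        geno = rng.integers(1, 5, size=(40, 1, 2))
        gm = make_gm(np.concatenate([geno, geno], axis=1))
        tr = linkage_disequilibrium_test(gm, "L0", "L1", reps=1000, seed=2)
        assert tr.p_value < 0.01

    def test_monomorphic_not_testable(self):
        rows = [[(1, 2), (7, 7)] for _ in range(10)]
        gm = make_gm(rows)
        tr = linkage_disequilibrium_test(gm, "L0", "L1", reps=1000, seed=3)
        assert tr.p_value is None and "not testable" in tr.flags

    def test_too_few_joint_individuals(self):
        rows = [[(1, 2), (3, 4)] for _ in range(4)]
        gm = make_gm(rows)
        tr = linkage_disequilibrium_test(gm, "L0", "L1", reps=1000, seed=4)
        assert "not testable" in tr.flags


def test_fisher_combination_is_a_probability():
    assert 0 <= combine_across_loci([0.2, 0.8, 0.5]) <= 1
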