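import numpy as np
import pytest

from conftest import make_gm
from coalpop.alignment import hamming_distance_matrix
from coalpop.datatypes import (
    GenotypeMatrix,
    HaplotypeTable,
    PopulationPartition,
    SequenceAlignment,
)
from coalpop.differentiation import (
    amova_fst,
    pairwise_fst_haplotype,
    pairwise_fst_microsat,
    pairwise_phist,
    permutation_pvalue,
    phist_permutation_test,
    shared_haplotype_matrix,
)
from coalpop.synth import (
    CoalescentScenario,
    SequenceMutationModel,
    mutate_sequences,
    simulate_split_sample,
)
from oracles import naive_amova_fst, naive_wc_theta


def _ht(counts_a, counts_b, pops=("A", "B")):
    H = len(counts_a)
    return HaplotypeTable(
        haplotype_sequences=[f"H{i}" for i in range(H)],
        counts=np.column_stack([counts_a, counts_b]),
        populations=list(pops),
    )


class TestHaplotypeFst:
    def test_complete_fixation(self):
        assert pairwise_fst_haplotype(_ht([4, 0], [0, 4]), "A", "B") == pytest.approx(
            1.0
        )

    def test_identical_spectra_non_positive(self):
        # with identical finite spectra the unbiased estimator is <= 0
        # (slightly negative, like any unbiased variance-component ratio)
        v = pairwise_fst_haplotype(_ht([3, 3], [3, 3]), "A", "B")
        assert -0.25 <= v <= 1e-9

    @pytest.mark.parametrize(
        "ca,cb", [([4, 0], [0, 4]), ([3, 1], [1, 3]), ([5, 2], [2, 6])]
    )
    def test_matches_bruteforce_amova(self, ca, cb):
        ht = _ht(ca, cb)
        hap_idx, labels = [], []
        for lab, counts in enumerate((ca, cb)):
            for h, c in enumerate(counts):
                hap_idx += [h] * c
                labels += [lab] * c
        hap_idx = np.array(hap_idx)
        d2 = (hap_idx[:, None] != hap_idx[None, :]).astype(float)
        expected = naive_amova_fst(d2, np.array(labels))
        assert pairwise_fst_haplotype(ht, "A", "B") == pytest.approx(
            expected, rel=1e-12
        )


class TestPhiST:
    def _toy(self):
        seqs = ["AAAA", "AAAT", "AATT", "TTTT", "TTTA", "TTAA"]
        ids = [f"s{i}" for i in range(6)]
        aln = SequenceAlignment(ids, seqs)
        part = PopulationPartition(
            {ids[i]: ("A" if i < 3 else "B") for i in range(6)}
        )
        return aln, part

    def test_fixed_differences_give_one(self):
        ids = [f"s{i}" for i in range(4)]
        aln = SequenceAlignment(ids, ["AAAC", "AAAC", "TTTC", "TTTC"])
        part = PopulationPartition({"s0": "A", "s1": "A", "s2": "B", "s3": "B"})
        assert pairwise_phist(aln, part, "A", "B") == pytest.approx(1.0)

    def test_toy_matches_bruteforce(self):
        aln, part = self._toy()
        d2 = hamming_distance_matrix(aln)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert pairwise_phist(aln, part, "A", "B") == pytest.approx(
            naive_amova_fst(d2, labels), rel=1e-12
        )

    def test_identity_distance_equals_haplotype_fst(self):
        aln, part = self._toy()
        ht_counts_a = [1, 1, 1, 0, 0, 0]
        ht_counts_b = [0, 0, 0, 1, 1, 1]
        ht = _ht(ht_counts_a, ht_counts_b)
        hap_idx = np.arange(6)
        d2 = (hap_idx[:, None] != hap_idx[None, :]).astype(float)
        assert amova_fst(d2, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(
            pairwise_fst_haplotype(ht, "A", "B"), rel=1e-12
        )

    def test_k2p_option_runs(self):
        ids = [f"s{i}" for i in range(6)]
        seqs = ["AAAAAAAAAA", "AAAAAAAAAG", "AAAAAAAAGG",
                "AAAAATAAAA", "AAAAATAAAG", "AAAAATTAAA"]
        aln = SequenceAlignment(ids, seqs)
        part = PopulationPartition(
            {ids[i]: ("A" if i < 3 else "B") for i in range(6)}
        )
        v = pairwise_phist(aln, part, "A", "B", distance_model="K2P")
        assert -1 <= v <= 1


class TestMicrosatFst:
    def test_fixed_loci_near_one(self):
        rows = [[(1, 1), (5, 5)]] * 8 + [[(9, 9), (2, 2)]] * 8
        gm = make_gm(rows)
        part = PopulationPartition(
            {f"i{k}": ("A" if k < 8 else "B") for k in range(16)}
        )
        assert pairwise_fst_microsat(gm, part, "A", "B") > 0.95

    def test_resample_near_zero(self):
        rng = np.random.default_rng(0)
        geno = rng.integers(1, 6, size=(60, 3, 2))
        gm = make_gm(geno)
        part = PopulationPartition(
            {f"i{k}": ("A" if k < 30 else "B") for k in range(60)}
        )
        assert abs(pairwise_fst_microsat(gm, part, "A", "B")) < 0.05

    def test_matches_bruteforce_theta(self):
        rng = np.random.default_rng(1)
        ga = rng.integers(1, 5, size=(12, 4, 2))
        gb = rng.integers(2, 7, size=(15, 4, 2))
        gm = make_gm(np.concatenate([ga, gb]))
        part = PopulationPartition(
            {f"i{k}": ("A" if k < 12 else "B") for k in range(27)}
        )
        assert pairwise_fst_microsat(gm, part, "A", "B") == pytest.approx(
            naive_wc_theta([ga, gb]), rel=1e-12
        )

    def test_island_model_expectation(self):
        """Two-deme split with migration: average theta near the island-model
        value FST = 1/(1 + 4 Nm d/(d-1)^2 ...) for d=2 -> 1/(1+16Nm)."""
        ne, m = 500, 0.002  # Nm = 1
        sc = CoalescentScenario(
            kind="split_migration", ne_a=ne, ne_b=ne, t_split=60000, m=m
        )
        rng = np.random.default_rng(42)
        model = SequenceMutationModel(mu_per_site=2e-6)
        vals = []
        for _ in range(60):
            tree = simulate_split_sample(30, 30, sc, rng)
            aln = mutate_sequences(tree, model, 600, rng)
            part = PopulationPartition(
                {aln.sample_ids[i]: ("A" if i < 30 else "B") for i in range(60)}
            )
            d2 = hamming_distance_matrix(aln)
            labels = np.array([0] * 30 + [1] * 30)
            vals.append(amova_fst(d2, labels))
        # d=2 islands: expected FST = 1/(1 + 4*Ne*m*(d/(d-1))^2) = 1/(1+16Nm)
        expected = 1.0 / (1.0 + 16 * ne * m)
        assert np.mean(vals) == pytest.approx(expected, abs=0.035)


class TestPermutationPvalue:
    def test_orientation_observed_below_null(self):
        rng = np.random.default_rng(2)
        labels = np.array([0] * 5 + [1] * 5)
        tr = permutation_pvalue(
            lambda lab: -1.0 if (lab == labels).all() else 1.0,
            labels,
            n_perm=200,
            seed=1,
        )
        assert tr.p_value > 0.9

    def test_fixed_difference_maximal_significance(self):
        ids = [f"s{i}" for i in range(12)]
        seqs = ["AAAA"] * 6 + ["TTTT"] * 6
        aln = SequenceAlignment(ids, seqs)
        d2 = hamming_distance_matrix(aln)
        labels = np.array([0] * 6 + [1] * 6)
        tr = phist_permutation_test(d2, labels, n_perm=1000, seed=3)
        assert tr.p_value < 0.01

    def test_degenerate_statistic_flagged(self):
        labels = np.array([0, 0, 1, 1])
        tr = permutation_pvalue(lambda lab: 0.0, labels, n_perm=100, seed=4)
        assert tr.p_value == 1.0 and "degenerate" in tr.flags

    def test_never_returns_zero(self):
        labels = np.array([0] * 4 + [1] * 4)
        tr = permutation_pvalue(
            lambda lab: float((lab == labels).all()), labels, n_perm=500, seed=5
        )
        assert tr.p_value >= 1 / 501

    def test_vectorised_matches_generic(self):
        rng = np.random.default_rng(6)
        seqs = ["".join(rng.choice(list("ACGT"), 20)) for _ in range(14)]
        aln = SequenceAlignment([f"s{i}" for i in range(14)], seqs)
        d2 = hamming_distance_matrix(aln)
        labels = np.array([0] * 7 + [1] * 7)
        fast = phist_permutation_test(d2, labels, n_perm=3000, seed=7)
        slow = permutation_pvalue(
            lambda lab: amova_fst(d2, lab), labels, n_perm=3000, seed=8
        )
        assert fast.statistic == pytest.approx(slow.statistic, rel=1e-12)
        assert fast.p_value == pytest.approx(slow.p_value, abs=0.03)


class TestSharedHaplotypes:
    def test_disjoint_sets(self):
        ht = _ht([2, 2, 0, 0], [0, 0, 2, 2])
        shared, private = shared_haplotype_matrix(ht)
        assert shared[0, 1] == 0
        assert private == {"A": 2, "B": 2}

    def test_identical_sets(self):
        ht = _ht([2, 2], [1, 3])
        shared, private = shared_haplotype_matrix(ht)
        assert shared[0, 1] == 2 and private == {"A": 0, "B": 0}

    def test_study_sharing_pattern(self):
        """Seven focal haplotypes: one shared with C; one with C,D; one with
        C,D,E; one with C,E,F; three private."""
        pops = ["ASHW", "C", "D", "E", "F"]
        counts = np.zeros((7, 5), dtype=int)
        counts[:, 0] = [18, 10, 8, 5, 3, 2, 1]
        counts[0, 1] = 5                       # shared with C
        counts[1, 1] = counts[1, 2] = 4        # shared with C and D
        counts[2, 1] = counts[2, 2] = counts[2, 3] = 3   # C, D, E
        counts[3, 1] = counts[3, 3] = counts[3, 4] = 2   # C, E, F
        ht = HaplotypeTable(
            haplotype_sequences=[f"H{i}" for i in range(7)],
            counts=counts,
            populations=pops,
        )
        shared, private = shared_haplotype_matrix(ht)
        row = {p: int(shared[0, j]) for j, p in enumerate(pops) if p != "ASHW"}
        assert row == {"C": 4, "D": 2, "E": 2, "F": 1}
        assert private["ASHW"] == 3


def test_fst_increases_with_divergence_time():
    """On simulated splits at fixed Ne, mean FST grows with divergence
    time (m = 0)."""
    rng = np.random.default_rng(77)
    model = SequenceMutationModel(mu_per_site=2e-6)
    means = []
    for t_split in (200, 5000):
        sc = CoalescentScenario(
            kind="split_migration", ne_a=500, ne_b=500, t_split=t_split, m=0.0
        )
        vals = []
        for _ in range(40):
            tree = simulate_split_sample(15, 15, sc, rng)
            aln = mutate_sequences(tree, model, 400, rng)
            d2 = hamming_distance_matrix(aln)
            vals.append(amova_fst(d2, np.array([0] * 15 + [1] * 15)))
        means.append(np.mean(vals))
    assert means[0] < means[1]
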