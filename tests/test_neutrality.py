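import numpy as np
import pytest

from coalpop.datatypes import SequenceAlignment, as_rng
from coalpop.neutrality import (
    coalescent_pvalue,
    mismatch_raggedness,
    r2_statistic,
    simulate_fixed_s,
    tajimas_d,
)
from coalpop.synth import simulate_sequences_theta
from oracles import naive_r2, naive_raggedness, naive_tajimas_d


def _aln(seqs):
    return SequenceAlignment([f"s{i}" for i in range(len(seqs))], seqs)


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        tr = tajimas_d(_aln(["ACGT", "ACGT"]))
        assert np.isnan(tr.statistic) and "undefined: S=0" in tr.flags

    def test_matches_bruteforce_on_simulated(self):
        rng = as_rng(10)
        for _ in range(20):
            aln = simulate_sequences_theta(10, 3.0, 200, rng)
            tr = tajimas_d(aln)
            if np.isnan(tr.statistic):
                continue
            assert tr.statistic == pytest.approx(
                naive_tajimas_d(aln.sequences), rel=1e-12
            )

    def test_two_clade_alignment_positive(self):
        """An excess of intermediate-frequency variants (two deep clades)
        pushes D above zero - the decline/structure signature."""
        seqs = ["AAAAAAAATT"] * 5 + ["TTTTTTTTTT"] * 5
        assert tajimas_d(_aln(seqs)).statistic > 0

    def test_site_permutation_invariance(self):
        seqs = ["AATT", "AATA", "TATA", "AAAA"]
        perm = ["".join(s[i] for i in (2, 0, 3, 1)) for s in seqs]
        assert tajimas_d(_aln(seqs)).statistic == pytest.approx(
            tajimas_d(_aln(perm)).statistic
        )


class TestR2:
    def test_two_sequences_single_difference(self):
        """n=2, one difference: both states are singletons, so U = (1, 1),
        k = 1, R2 = 0.5 - verified against the brute-force oracle."""
        aln = _aln(["AAAA", "AAAT"])
        tr = r2_statistic(aln)
        assert tr.statistic == pytest.approx(0.5)
        assert tr.statistic == pytest.approx(naive_r2(aln.sequences))

    def test_in_unit_interval(self):
        rng = as_rng(11)
        for _ in range(10):
            aln = simulate_sequences_theta(12, 4.0, 300, rng)
            tr = r2_statistic(aln)
            if not np.isnan(tr.statistic):
                assert 0 < tr.statistic <= 1

    def test_matches_bruteforce_on_simulated(self):
        rng = as_rng(12)
        for _ in range(20):
            aln = simulate_sequences_theta(8, 3.0, 200, rng)
            tr = r2_statistic(aln)
            if np.isnan(tr.statistic):
                continue
            assert tr.statistic == pytest.approx(
                naive_r2(aln.sequences), rel=1e-12
            )


class TestMismatchRaggedness:
    def test_single_class_zero(self):
        freqs, rg = mismatch_raggedness(_aln(["AAAA"] * 4))
        assert rg == 0.0 and freqs.tolist() == [1.0]

    def test_two_equal_classes_zero(self):
        # three of six pairs identical, three differ at one site:
        # x0 = x1 = 0.5 -> rg = 0
        freqs, rg = mismatch_raggedness(_aln(["AA", "AA", "AA", "AT"]))
        assert freqs.tolist() == [0.5, 0.5] and rg == pytest.approx(0.0)

    def test_matches_bruteforce_on_simulated(self):
        rng = as_rng(13)
        for _ in range(10):
            aln = simulate_sequences_theta(10, 4.0, 300, rng)
            _, rg = mismatch_raggedness(aln)
            assert rg == pytest.approx(naive_raggedness(aln.sequences), rel=1e-12)

    def test_structured_more_ragged_than_smooth(self):
        rng = as_rng(14)
        smooth, ragged = [], []
        for _ in range(25):
            smooth.append(mismatch_raggedness(
                simulate_sequences_theta(20, 8.0, 400, rng))[1])
            two_clades = ["A" * 20 + "T" * 10] * 10 + ["T" * 20 + "A" * 10] * 10
            ragged.append(mismatch_raggedness(_aln(two_clades))[1])
        assert np.mean(smooth) < np.mean(ragged)


class TestCoalescentPvalue:
    def test_fixed_s_conditioning(self):
        rng = as_rng(15)
        for _ in range(20):
            X = simulate_fixed_s(8, 5, rng)
            assert X.shape == (8, 5)
            counts = X.sum(axis=0)
            assert ((counts >= 1) & (counts <= 7)).all()

    def test_null_median_p_near_half(self):
        rng = as_rng(16)
        cache = {}
        tr = coalescent_pvalue("D", 0.0, 20, 10, reps=2000, seed=1,
                               tail="upper", null_cache=cache)
        # D = 0 sits near the centre of the null
        assert 0.25 < tr.p_value < 0.75

    def test_upper_tail_orientation(self):
        tr = coalescent_pvalue("D", 10.0, 20, 10, reps=500, seed=2, tail="upper")
        assert tr.p_value == pytest.approx(1 / 501)
        tr2 = coalescent_pvalue("D", 10.0, 20, 10, reps=500, seed=2, tail="lower")
        assert tr2.p_value == 1.0

    def test_two_sided_doubles(self):
        up = coalescent_pvalue("D", 1.5, 15, 8, reps=800, seed=3, tail="upper")
        two = coalescent_pvalue("D", 1.5, 15, 8, reps=800, seed=3, tail="two-sided")
        assert two.p_value <= 1.0 and two.p_value >= up.p_value

    def test_s_zero_errors(self):
        with pytest.raises(ValueError):
            coalescent_pvalue("D", 0.0, 10, 0, reps=100, seed=4)
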