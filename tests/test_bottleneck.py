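import numpy as np
import pytest

from conftest import make_gm
from coalpop.bottleneck import (
    CONSERVATIVE_TPM,
    REALISTIC_TPM,
    TwoPhaseModel,
    het_excess_test,
    m_ratio,
    m_ratio_verdict,
    mode_shift_test,
    prebottleneck_ne,
    simulate_mc,
)
from coalpop.synth import simulate_microsat_dataset


def _single_locus_gm(alleles):
    rows = [[(a, a)] for a in alleles]
    return make_gm(rows)


class TestMRatio:
    def test_full_ladder(self):
        res = m_ratio(_single_locus_gm([10, 11, 12]))
        assert res.mean == pytest.approx(1.0)

    def test_gap_in_ladder(self):
        res = m_ratio(_single_locus_gm([10, 11, 13]))
        assert res.mean == pytest.approx(0.75)

    def test_shift_invariance(self):
        a = m_ratio(_single_locus_gm([10, 11, 13])).mean
        b = m_ratio(_single_locus_gm([110, 111, 113])).mean
        assert a == pytest.approx(b)

    def test_monomorphic_excluded_with_warning(self):
        rows = [[(5, 5), (10, 11)], [(5, 5), (11, 12)]]
        gm = make_gm(rows)
        with pytest.warns(UserWarning):
            res = m_ratio(gm)
        assert list(res.per_locus) == ["L1"]

    def test_all_monomorphic_errors(self):
        with pytest.warns(UserWarning), pytest.raises(ValueError):
            m_ratio(_single_locus_gm([7, 7, 7]))


class TestTwoPhaseModel:
    @pytest.mark.parametrize("kw", [
        {"ps": 0.0, "delta_g": 3.5},
        {"ps": 0.9, "delta_g": 1.0},
        {"ps": 0.9, "delta_g": 3.5, "theta": 0.0},
    ])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            TwoPhaseModel(**kw)


class TestSimulateMc:
    def test_pure_stepwise_tiny_theta_near_one(self):
        tpm = TwoPhaseModel(ps=1.0, delta_g=2.5, theta=0.004)
        res = simulate_mc(40, 5, tpm, theta_grid=(0.004,), reps=300, seed=1)
        assert res.mc[0] > 0.95

    def test_mc_decreases_with_delta_g(self):
        """Larger multistep jumps punch holes in the allelic ladder."""
        small = simulate_mc(
            60, 8, TwoPhaseModel(ps=0.8, delta_g=2.2),
            theta_grid=(2.0,), reps=400, seed=2,
        )
        large = simulate_mc(
            60, 8, TwoPhaseModel(ps=0.8, delta_g=5.0),
            theta_grid=(2.0,), reps=400, seed=2,
        )
        assert large.mc[0] < small.mc[0]

    def test_curve_non_increasing_paired_seeds(self):
        tpm = TwoPhaseModel(**REALISTIC_TPM)
        res = simulate_mc(60, 8, tpm, reps=300, seed=3)
        assert (np.diff(res.mc) <= 1e-9).all()

    def test_invalid_grid(self):
        tpm = TwoPhaseModel(**CONSERVATIVE_TPM)
        with pytest.raises(ValueError):
            simulate_mc(40, 5, tpm, theta_grid=(0.0, 1.0), reps=10, seed=0)


class TestVerdict:
    def _result(self):
        tpm = TwoPhaseModel(**CONSERVATIVE_TPM)
        res = simulate_mc(40, 5, tpm, theta_grid=(0.5, 1.0), reps=200, seed=4)
        return res

    def test_observed_one_never_indicates(self):
        v = m_ratio_verdict(self._result(), 1.0)
        assert not any(v["indicated"]) and v["theta_star"] is None

    @pytest.mark.parametrize(
        "theta_star,expected", [(4.2, 2100.0), (1.1, 550.0)]
    )
    def test_prebottleneck_ne_conversion(self, theta_star, expected):
        assert prebottleneck_ne(theta_star, mu=5e-4) == pytest.approx(expected)

    def test_ne_linear_in_theta(self):
        assert prebottleneck_ne(2.0) == pytest.approx(2 * prebottleneck_ne(1.0))

    def test_out_of_range_m_errors(self):
        with pytest.raises(ValueError):
            m_ratio_verdict(self._result(), 1.5)


class TestHetExcess:
    def test_too_few_loci_errors(self):
        gm = make_gm([[(1, 1)], [(1, 1)]])
        tpm = TwoPhaseModel(**CONSERVATIVE_TPM)
        with pytest.raises(ValueError):
            het_excess_test(gm, tpm, reps=50, seed=0)

    def test_returns_valid_probability(self):
        rng = np.random.default_rng(9)
        gm = simulate_microsat_dataset(30, 6, 1.0, 0.9, 3.5, rng)
        tpm = TwoPhaseModel(**CONSERVATIVE_TPM)
        tr = het_excess_test(gm, tpm, reps=150, seed=1)
        assert 0 < tr.p_value <= 1
        assert tr.method == "coalescent"
        assert tr.extras["n_loci"] >= 2


class TestModeShift:
    def test_constructed_shifted_spectrum(self):
        # 8 loci diallelic at 15/85%: every allele sits in classes 2 and 9
        rows = []
        for i in range(20):
            rows.append([(1, 1) if i < 14 else (2, 2) for _ in range(8)])
        gm = make_gm(rows)
        counts, l_shaped = mode_shift_test(gm)
        assert not l_shaped

    def test_fifty_fifty_diallelic_single_locus(self):
        rows = [[(1, 1)]] * 5 + [[(2, 2)]] * 5
        counts, l_shaped = mode_shift_test(make_gm(rows))
        assert counts[4] == 2 and not l_shaped  # both alleles in (0.4, 0.5]

    def test_equilibrium_fixture_l_shaped(self):
        rng = np.random.default_rng(4)
        gm = simulate_microsat_dataset(47, 11, 2.0, 0.9, 3.5, rng)
        counts, l_shaped = mode_shift_test(gm)
        assert l_shaped

    def test_no_polymorphic_loci_errors(self):
        with pytest.raises(ValueError):
            mode_shift_test(make_gm([[(1, 1)], [(1, 1)]]))
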