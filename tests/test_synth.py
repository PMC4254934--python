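import numpy as np
import pytest

from coalpop.alignment import collapse_haplotypes, segregating_sites
from coalpop.datatypes import as_rng
from coalpop.diversity import locus_summaries
from coalpop.synth import (
    CoalescentScenario,
    InfiniteSitesOverflow,
    SequenceMutationModel,
    make_ashw_fixture,
    msat_leaf_sizes,
    mutate_sequences,
    simulate_genealogy,
    simulate_split_sample,
    simulate_sequences_theta,
    tpm_steps,
    unit_tree,
)


class TestScenarios:
    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            CoalescentScenario(kind="constant", ne=0)
        with pytest.raises(ValueError):
            CoalescentScenario(kind="weird")
        with pytest.raises(ValueError):
            CoalescentScenario(
                kind="split_migration", ne_a=10, ne_b=10, t_split=5, m=1.5
            )


class TestGenealogy:
    def test_tmrca_exponential_mean(self):
        """n=2, constant Ne: TMRCA ~ Exp(mean 2Ne generations)."""
        sc = CoalescentScenario(kind="constant", ne=100)
        rng = as_rng(1)
        t = np.array([simulate_genealogy(2, sc, rng).tmrca() for _ in range(4000)])
        se = t.std(ddof=1) / np.sqrt(len(t))
        assert abs(t.mean() - 200) < 3 * se + 1e-9

    def test_bottleneck_shortens_tmrca(self):
        """Paired-seed comparison against the matched constant-ancestral
        control."""
        bn = CoalescentScenario(
            kind="bottleneck", ne_anc=1000, ne_post=10, t_bottleneck=50
        )
        ct = CoalescentScenario(kind="constant", ne=1000)
        t_bn = np.mean(
            [simulate_genealogy(10, bn, s).tmrca() for s in range(300)]
        )
        t_ct = np.mean(
            [simulate_genealogy(10, ct, s).tmrca() for s in range(300)]
        )
        assert t_bn < t_ct

    def test_split_without_migration_structures_coalescence(self):
        sc = CoalescentScenario(
            kind="split_migration", ne_a=50, ne_b=50, t_split=500, m=0.0
        )
        rng = as_rng(2)
        for _ in range(30):
            tree = simulate_split_sample(4, 4, sc, rng)
            M = tree.leaf_matrix()
            demes = tree.leaf_population
            for node in range(tree.n_leaves, tree.n_nodes):
                under = demes[M[node, : tree.n_leaves]]
                if len(set(under.tolist())) > 1:
                    assert tree.time[node] >= 500

    def test_deterministic_under_seed(self):
        sc = CoalescentScenario(kind="constant", ne=42)
        a = simulate_genealogy(12, sc, 7)
        b = simulate_genealogy(12, sc, 7)
        assert np.array_equal(a.parent, b.parent)
        assert np.array_equal(a.time, b.time)


class TestSequenceMutation:
    def test_rate_zero_identical_sequences(self):
        tree = unit_tree(6, as_rng(3))
        aln = mutate_sequences(tree, SequenceMutationModel(mu_per_site=0.0), 50, 4)
        assert len(set(aln.sequences)) == 1

    def test_infinite_sites_overflow(self):
        tree = unit_tree(10, as_rng(5))
        model = SequenceMutationModel(mu_per_site=50.0)
        with pytest.raises(InfiniteSitesOverflow):
            mutate_sequences(tree, model, 3, 6)

    def test_k2p_mode_produces_alignment(self):
        tree = unit_tree(8, as_rng(6))
        model = SequenceMutationModel(mu_per_site=0.05, mode="k2p", kappa=4.0)
        aln = mutate_sequences(tree, model, 100, 7)
        assert aln.n == 8 and aln.length == 100

    def test_mean_k_equals_theta(self):
        """E[mean pairwise differences] = theta on the constant-size
        coalescent."""
        from coalpop.diversity import mean_pairwise_differences

        rng = as_rng(8)
        theta = 4.0
        ks = []
        for _ in range(1500):
            aln = simulate_sequences_theta(8, theta, 300, rng)
            ks.append(mean_pairwise_differences(aln)[0])
        ks = np.array(ks)
        se = ks.std(ddof=1) / np.sqrt(len(ks))
        assert abs(ks.mean() - theta) < 3.5 * se


class TestMicrosatMutation:
    def test_tpm_step_magnitudes(self):
        rng = as_rng(9)
        steps = tpm_steps(20000, 0.8, 3.5, rng)
        mags = np.abs(steps)
        assert set(np.unique(np.sign(steps))) == {-1, 1}
        assert (mags[mags > 1] >= 2).all()
        multi = mags[mags > 1]
        assert multi.mean() == pytest.approx(3.5, abs=0.15)

    def test_rate_zero_monomorphic(self):
        tree = unit_tree(12, as_rng(10))
        sizes = msat_leaf_sizes(tree, 0.0, 0.9, 3.5, as_rng(11))
        assert (sizes == 20).all()

    def test_smm_variance_grows_with_theta(self):
        """Pure stepwise mutation: allele-size variance increases with
        theta (regression over a grid, paired seeds)."""
        grid = [0.5, 2.0, 8.0]
        means = []
        for theta in grid:
            rng = as_rng(12)
            v = []
            for _ in range(300):
                tree = unit_tree(30, rng)
                sizes = msat_leaf_sizes(tree, theta / 2.0, 1.0, 2.5, rng)
                v.append(sizes.var())
            means.append(np.mean(v))
        assert means[0] < means[1] < means[2]

    def test_reflection_keeps_sizes_above_floor(self):
        rng = as_rng(13)
        for _ in range(50):
            tree = unit_tree(20, rng)
            sizes = msat_leaf_sizes(tree, 10.0, 0.7, 6.0, rng, root_size=4)
            assert (sizes >= 2).all()


class TestFixture:
    def test_structural_counts(self, ashw):
        aln, gm, part = ashw
        assert aln.n == gm.n == 47
        assert segregating_sites(aln)[0] == 24
        assert collapse_haplotypes(aln, part).n_haplotypes == 7
        summary = locus_summaries(gm)
        assert summary["K"].min() == 3 and summary["K"].max() == 12
        assert summary.loc["EV37Mn", "K"] == 12
        assert summary.loc["EV1Pm", "K"] == 3
        assert gm.missing_fraction() <= 0.003

    def test_deterministic(self):
        a1, g1, _ = make_ashw_fixture(seed=0)
        a2, g2, _ = make_ashw_fixture(seed=0)
        assert a1.sequences == a2.sequences
        assert np.array_equal(g1.alleles, g2.alleles)

    def test_raw_variant_counts(self, ashw_raw):
        _, gm, _ = ashw_raw
        assert gm.n == 67
        failed = (gm.alleles[:, :, 0] == 0).all(axis=1)
        assert failed.sum() == 4


def test_watterson_and_msprime_cross_check():
    """Our simulator's E[S] agrees with both the closed form and an msprime
    simulation at matched parameters (independent coalescent oracle)."""
    import msprime

    from coalpop.alignment import segregating_sites as segsites

    theta, n, L, reps = 5.0, 10, 400, 1500
    rng = as_rng(20)
    ours = np.array(
        [segsites(simulate_sequences_theta(n, theta, L, rng))[0] for b in range(reps)]
    )
    ms = np.array(
        [
            msprime.sim_mutations(
                ts, rate=theta / 2.0, discrete_genome=False
            ).num_sites
            for ts in msprime.sim_ancestry(
                samples=n,
                ploidy=1,
                population_size=1.0,
                num_replicates=reps,
                random_seed=99,
            )
        ]
    )
    closed = theta * sum(1 / i for i in range(1, n))
    se = ours.std(ddof=1) / np.sqrt(reps)
    assert abs(ours.mean() - closed) < 3.5 * se
    assert abs(ours.mean() - ms.mean()) < 4 * np.sqrt(
        ours.var() / reps + ms.var() / reps
    )
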