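#!/usr/bin/env python
"""Pairwise differentiation between the focal population and a simulated
comparison population.

Simulates a second population connected by an ancient split with limited
migration, then computes haplotype FST, PhiST (10,000 permutations) and
microsatellite Weir-Cockerham FST, plus the shared/private haplotype
summary.  Writes results/differentiation.json.
"""

import json
from pathlib import Path

import numpy as np

from coalpop.alignment import collapse_haplotypes, hamming_distance_matrix
from coalpop.datatypes import PopulationPartition, SequenceAlignment
from coalpop.differentiation import (
    pairwise_fst_haplotype,
    pairwise_fst_microsat,
    phist_permutation_test,
    shared_haplotype_matrix,
)
from coalpop.io import read_fasta_alignment, read_genepop
from coalpop.synth import (
    CoalescentScenario,
    SequenceMutationModel,
    mutate_microsats,
    mutate_sequences,
    simulate_genealogy,
    simulate_split_sample,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "synthetic"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    focal_aln = read_fasta_alignment(DATA / "sequences.fasta")
    gm, _ = read_genepop(DATA / "genotypes_screened.gen", DATA / "loci.yaml")
    n_focal = focal_aln.n

    # comparison population: ancient split, weak gene flow (the regime the
    # focal population's isolation hypothesis implies)
    sc = CoalescentScenario(
        kind="split_migration", ne_a=8000, ne_b=8000, t_split=3000, m=5e-5
    )
    tree = simulate_split_sample(n_focal, 100, sc, rng)
    model = SequenceMutationModel(mu_per_site=5.2e-8 * 21.5)  # per generation
    both = mutate_sequences(tree, model, 486, rng, id_prefix="sim")
    ids = both.sample_ids
    part = PopulationPartition(
        {ids[i]: ("focal" if i < n_focal else "comparison") for i in range(len(ids))}
    )
    ht = collapse_haplotypes(both, part)
    fst_h = pairwise_fst_haplotype(ht, "focal", "comparison")
    d2 = hamming_distance_matrix(both)
    labels = np.array([part.assignments[s] for s in ids])
    phist = phist_permutation_test(d2, labels, n_perm=10_000, seed=SEED)
    shared, private = shared_haplotype_matrix(ht)

    # microsatellites: same split scenario, diploid trees per locus
    trees = [
        simulate_split_sample(2 * n_focal, 2 * 100, sc, rng)
        for _ in range(gm.n_loci)
    ]
    gm_both = mutate_microsats(trees, 5e-4, 0.88, 2.8, rng)
    gpart = PopulationPartition(
        {
            s: ("focal" if i < n_focal else "comparison")
            for i, s in enumerate(gm_both.sample_ids)
        }
    )
    fst_ms = pairwise_fst_microsat(gm_both, gpart, "focal", "comparison")

    print(f"haplotype FST = {fst_h:.4f}")
    print(f"PhiST = {phist.statistic:.4f} (p = {phist.p_value:.4g}, "
          f"{phist.n_reps} permutations)")
    print(f"microsatellite FST (Weir-Cockerham) = {fst_ms:.4f}")
    print(f"shared haplotypes focal vs comparison: {int(shared[0, 1])}; "
          f"private: {private}")

    (RESULTS / "differentiation.json").write_text(
        json.dumps(
            {
                "FST_haplotype": fst_h,
                "PhiST": phist.statistic,
                "PhiST_p": phist.p_value,
                "FST_microsat": fst_ms,
                "shared": int(shared[0, 1]),
                "private": private,
                "scenario": {"ne": 8000, "t_split": 3000, "m": 5e-5},
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
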