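#!/usr/bin/env python
"""Within-population diversity and locus quality.

Sequence side: haplotype count, polymorphic sites, haplotype diversity Hd
and mean pairwise differences k.  Microsatellite side: per-locus K, Ho,
He, HWE probability tests (with a Fisher combination across loci) and all
pairwise LD tests.  Writes results/diversity_loci.tsv and
results/diversity.json.
"""

import itertools
import json
from pathlib import Path

from coalpop.alignment import collapse_haplotypes, segregating_sites
from coalpop.datatypes import PopulationPartition
from coalpop.diversity import (
    combine_across_loci,
    haplotype_diversity,
    hwe_probability_test,
    linkage_disequilibrium_test,
    locus_summaries,
    mean_pairwise_differences,
)
from coalpop.io import read_fasta_alignment, read_genepop

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "synthetic"
RESULTS = ROOT / "results"
SEED = 0


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    aln = read_fasta_alignment(DATA / "sequences.fasta")
    part = PopulationPartition({s: "focal" for s in aln.sample_ids})
    ht = collapse_haplotypes(aln, part)
    hd, hd_sd = haplotype_diversity(ht, "focal")
    k, k_sd = mean_pairwise_differences(aln)
    S, _ = segregating_sites(aln)
    print(f"mtDNA: n={aln.n}, {ht.n_haplotypes} haplotypes, S={S}")
    print(f"  Hd = {hd:.4f} +- {hd_sd:.4f}; k = {k:.4f} +- {k_sd:.4f}")

    gm, _ = read_genepop(DATA / "genotypes_screened.gen", DATA / "loci.yaml")
    summary = locus_summaries(gm)
    summary.to_csv(RESULTS / "diversity_loci.tsv", sep="\t")
    print(
        f"microsatellites: mean K = {summary['K'].mean():.2f}, "
        f"Ho = {summary['Ho'].mean():.3f}, He = {summary['He'].mean():.3f}"
    )

    hwe = {
        locus: hwe_probability_test(gm, locus, reps=10_000, seed=SEED).p_value
        for locus in gm.locus_names
    }
    fisher = combine_across_loci([p for p in hwe.values() if p is not None])
    print(f"HWE across loci (Fisher): p = {fisher:.3f}")

    ld_p = {}
    for a, b in itertools.combinations(gm.locus_names, 2):
        tr = linkage_disequilibrium_test(gm, a, b, reps=2000, seed=SEED)
        if tr.p_value is not None:
            ld_p[f"{a}|{b}"] = tr.p_value
    n_sig = sum(p <= 0.05 for p in ld_p.values())
    print(f"LD: {n_sig}/{len(ld_p)} locus pairs nominally significant at 0.05")

    (RESULTS / "diversity.json").write_text(
        json.dumps(
            {
                "sequence": {"n": aln.n, "haplotypes": ht.n_haplotypes, "S": S,
                             "Hd": hd, "Hd_sd": hd_sd, "k": k, "k_sd": k_sd},
                "microsat": summary.to_dict(orient="index"),
                "hwe": hwe,
                "hwe_fisher": fisher,
                "ld": ld_p,
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
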