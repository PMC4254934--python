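#!/usr/bin/env python
"""Identity screening of the raw genotype file.

Drops samples with no amplifiable data, removes genotype-identical
re-samples, and reports the probability of identity justifying the
removals.  Writes the screened Genepop file and a TSV duplicate report to
results/.
"""

import csv
from pathlib import Path

from coalpop.datatypes import PopulationPartition
from coalpop.identity import probability_of_identity, screen_duplicates
from coalpop.io import read_genepop, write_genepop

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "synthetic"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    gm, part = read_genepop(DATA / "genotypes_raw.gen", DATA / "loci.yaml")
    screened, removed, pairs = screen_duplicates(gm)
    per_locus, pi = probability_of_identity(screened)
    n_pairs = screened.n * (screened.n - 1) // 2
    write_genepop(
        screened,
        PopulationPartition({s: "focal" for s in screened.sample_ids}),
        DATA / "genotypes_screened.gen",
    )
    with open(RESULTS / "duplicates.tsv", "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["sample_a", "sample_b", "mismatch_loci", "compared_loci"])
        for p in pairs:
            w.writerow([p.sample_a, p.sample_b, p.mismatch_loci, p.compared_loci])
    print(f"{gm.n} raw records -> {screened.n} unique individuals")
    print(f"removed: {len(removed)} ({len(pairs)} duplicate pairs)")
    print(
        f"overall PI = {pi:.3g}; threshold for confident exclusion "
        f"1/{n_pairs} = {1/n_pairs:.3g} -> "
        f"{'confident' if pi < 1/n_pairs else 'NOT confident'}"
    )


if __name__ == "__main__":
    main()
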