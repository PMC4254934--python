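#!/usr/bin/env python
"""Generate the synthetic study-scale dataset.

Writes the raw variant (67 genotype records: 47 individuals, 16 planted
re-samples, 4 failed extractions) plus the 47-sequence mtDNA alignment to
data/synthetic/, in the interchange formats the rest of the chain reads
(FASTA, Genepop, YAML sidecars).
"""

from pathlib import Path

from coalpop.io import (
    write_fasta_alignment,
    write_genepop,
    write_locus_config,
    write_partition_yaml,
)
from coalpop.synth import make_ashw_fixture

OUT = Path(__file__).resolve().parent.parent / "data" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    aln, gm_raw, part_raw = make_ashw_fixture(seed=0, raw=True)
    write_fasta_alignment(aln, OUT / "sequences.fasta")
    write_genepop(gm_raw, part_raw, OUT / "genotypes_raw.gen")
    write_locus_config(gm_raw, OUT / "loci.yaml")
    write_partition_yaml(part_raw, OUT / "partition.yaml")
    print(
        f"wrote {gm_raw.n} raw genotype records and {aln.n} sequences to {OUT}"
    )
    print("16 duplicates and 4 failed samples are planted for 02_screen.")


if __name__ == "__main__":
    main()
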