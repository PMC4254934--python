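#!/usr/bin/env python
"""Convenience fetcher for the deposited mtDNA control-region haplotypes.

Downloads the seven focal-population accessions (GQ913845, GQ913846,
GQ913848, GQ913701, GQ913706, GQ913709, GQ913715) from GenBank and writes
them to a FASTA file.  Requires network access; the library itself never
depends on this script — offline workflows use the synthetic fixture
instead.

Usage: python scripts/fetch_genbank_haplotypes.py --out data/ashw_haplotypes.fasta
"""

import argparse
import sys

ACCESSIONS = [
    "GQ913845",
    "GQ913846",
    "GQ913848",
    "GQ913701",
    "GQ913706",
    "GQ913709",
    "GQ913715",
]


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default="ashw_haplotypes.fasta")
    parser.add_argument("--email", default="anonymous@example.org",
                        help="contact email for NCBI E-utilities")
    args = parser.parse_args()

    from Bio import Entrez, SeqIO

    Entrez.email = args.email
    with Entrez.efetch(
        db="nuccore", id=",".join(ACCESSIONS), rettype="fasta", retmode="text"
    ) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != len(ACCESSIONS):
        print(f"expected {len(ACCESSIONS)} records, got {len(records)}",
              file=sys.stderr)
        return 1
    SeqIO.write(records, args.out, "fasta")
    print(f"wrote {len(records)} sequences to {args.out}")
    print("align over the 486-bp consensus before computing site statistics")
    return 0


if __name__ == "__main__":
    sys.exit(main())
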