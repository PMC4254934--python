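"""File I/O: FASTA alignments, Genepop genotypes, sidecar locus config.

Genepop cannot encode repeat-motif lengths, so they travel in a YAML sidecar
(`loci: [{name, motif_length}, ...]`).  Allele codes are repeat units by
default; a sidecar may declare ``units: bp`` per locus, in which case sizes
are divided by the motif length on input.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import (
    MISSING,
    VALID_SEQ_CHARS,
    AlignmentError,
    GenotypeMatrix,
    IdentityError,
    PopulationPartition,
    SequenceAlignment,
    warn,
)


class GenepopParseError(ValueError):
    """Malformed Genepop file; message carries the 1-based line number."""


def read_fasta_alignment(path: str | Path) -> SequenceAlignment:
    """Read an aligned FASTA file.

    Characters are uppercased; anything outside {A,C,G,T,-,N} is mapped to N
    with a warning.  Unequal lengths raise :class:`AlignmentError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise IdentityError(f"duplicate record ids in {path}")
    seqs = []
    mapped_any = False
    for r in records:
        s = str(r.seq).upper()
        bad = set(s) - VALID_SEQ_CHARS
        if bad:
            mapped_any = True
            s = "".join(c if c in VALID_SEQ_CHARS else "N" for c in s)
        seqs.append(s)
    if mapped_any:
        warn(f"unknown characters in {path} mapped to N")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise AlignmentError(
            f"unequal sequence lengths in {path}: {sorted(lengths)}"
        )
    return SequenceAlignment(sample_ids=ids, sequences=seqs)


def write_fasta_alignment(aln: SequenceAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_locus_config(path: str | Path) -> dict:
    """Sidecar YAML: ``loci: [{name, motif_length, units?}, ...]``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "loci" not in cfg:
        raise ValueError(f"locus config {path} must contain a 'loci' list")
    return cfg


def write_locus_config(gm: GenotypeMatrix, path: str | Path) -> None:
    cfg = {
        "loci": [
            {"name": name, "motif_length": int(m)}
            for name, m in zip(gm.locus_names, gm.motif_lengths)
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _decode_genotype(token: str, lineno: int) -> tuple[int, int]:
    if len(token) == 4:
        w = 2
    elif len(token) == 6:
        w = 3
    else:
        raise GenepopParseError(
            f"line {lineno}: genotype token '{token}' is neither 4 nor 6 digits"
        )
    if not token.isdigit():
        raise GenepopParseError(f"line {lineno}: non-numeric genotype '{token}'")
    a, b = int(token[:w]), int(token[w:])
    if (a == 0) != (b == 0):
        # half-missing genotypes are treated as fully missing
        a = b = 0
    return a, b


def read_genepop(
    path: str | Path, locus_config: str | Path | dict | None = None
) -> tuple[GenotypeMatrix, PopulationPartition]:
    """Parse a Genepop v4 dialect file.

    Layout: title line; one locus name per line (or a single comma-separated
    line); populations separated by lines equal to ``POP`` (case-insensitive);
    individual lines ``name , g1 g2 ...`` with 2- or 3-digit allele codes and
    00/000 as missing.  Population labels default to pop1, pop2, ...
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise GenepopParseError("file too short for Genepop format")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        chunk = lines[i].strip()
        if chunk:
            locus_names.extend(x.strip() for x in chunk.split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise GenepopParseError("no POP separator found")
    if not locus_names:
        raise GenepopParseError("no locus names before first POP")

    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    rows: list[list[tuple[int, int]]] = []
    pop_index = 0
    for lineno in range(i, len(lines)):
        raw = lines[lineno].strip()
        if not raw:
            continue
        if raw.upper() == "POP":
            pop_index += 1
            continue
        if "," in raw:
            name, geno_part = raw.split(",", 1)
        else:
            raise GenepopParseError(
                f"line {lineno + 1}: individual line lacks ',' separator"
            )
        name = name.strip()
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                f"line {lineno + 1}: {len(tokens)} genotypes for "
                f"{len(locus_names)} loci"
            )
        genos = [_decode_genotype(t, lineno + 1) for t in tokens]
        if name in assignments:
            raise IdentityError(f"duplicate individual name '{name}'")
        sample_ids.append(name)
        assignments[name] = f"pop{pop_index}"
        rows.append(genos)

    if not rows:
        raise GenepopParseError("no individuals parsed")
    alleles = np.array(rows, dtype=int)  # (n, L, 2)

    motifs = np.full(len(locus_names), 2, dtype=int)
    if locus_config is not None:
        cfg = (
            locus_config
            if isinstance(locus_config, dict)
            else read_locus_config(locus_config)
        )
        by_name = {d["name"]: d for d in cfg["loci"]}
        for j, ln in enumerate(locus_names):
            if ln in by_name:
                motifs[j] = int(by_name[ln]["motif_length"])
                if by_name[ln].get("units", "repeats") == "bp":
                    col = alleles[:, j, :]
                    nz = col != MISSING
                    col[nz] = np.maximum(col[nz] // motifs[j], 1)
            else:
                warn(f"locus {ln} missing from sidecar config; motif=2 assumed")
    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        locus_names=locus_names,
        motif_lengths=motifs,
        alleles=alleles,
    )
    return gm, PopulationPartition(assignments=assignments)


def write_genepop(
    gm: GenotypeMatrix,
    part: PopulationPartition,
    path: str | Path,
    title: str = "coalpop export",
) -> None:
    """Write Genepop with 3-digit codes, grouping individuals by population."""
    if int(gm.alleles.max(initial=0)) > 999:
        raise ValueError("allele size exceeds 3-digit Genepop code")
    out = [title]
    out.extend(gm.locus_names)
    index = {s: i for i, s in enumerate(gm.sample_ids)}
    for pop in part.populations:
        out.append("POP")
        for s in part.samples(pop):
            if s not in index:
                continue
            row = gm.alleles[index[s]]
            tokens = [f"{a:03d}{b:03d}" for a, b in row]
            out.append(f"{s} , " + " ".join(tokens))
    Path(path).write_text("\n".join(out) + "\n")


def read_partition_yaml(path: str | Path) -> PopulationPartition:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PopulationPartition(assignments={str(k): str(v) for k, v in data.items()})


def write_partition_yaml(part: PopulationPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(part.assignments), fh, sort_keys=False)
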