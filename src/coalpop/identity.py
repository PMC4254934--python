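"""Sample-identity screening: probability of identity and duplicate detection.

A multi-locus genotype is a near-unique individual tag; before any
population-level statistic we (i) quantify how unique (PI) and (ii) remove
re-sampled individuals whose genotypes match at every comparable locus.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import MISSING, GenotypeMatrix, warn

logger = logging.getLogger(__name__)


def probability_of_identity(gm: GenotypeMatrix) -> tuple[dict[str, float], float]:
    """Per-locus and overall probability that two random individuals share a
    genotype by chance under HWE.

    PI_l = 2 (sum p_i^2)^2 - sum p_i^4; overall PI is the product over loci
    (independence).  Loci with no data are excluded with a warning.
    """
    per_locus: dict[str, float] = {}
    overall = 1.0
    for j, name in enumerate(gm.locus_names):
        freqs = gm.allele_frequencies(j)
        if not freqs:
            warn(f"locus {name} entirely missing; excluded from PI")
            continue
        p = np.array(list(freqs.values()))
        pi = 2.0 * (p**2).sum() ** 2 - (p**4).sum()
        per_locus[name] = float(pi)
        overall *= float(pi)
    if not per_locus:
        raise ValueError("no locus with data for PI")
    return per_locus, overall


@dataclass
class DuplicatePair:
    sample_a: str
    sample_b: str
    mismatch_loci: int
    compared_loci: int


def find_duplicates(
    gm: GenotypeMatrix, max_mismatch_loci: int = 0
) -> list[DuplicatePair]:
    """All unordered pairs matching at every mutually genotyped locus except
    at most ``max_mismatch_loci``.

    Pairs with zero comparable loci are never reported.  The overall PI is
    logged against the number of pairwise comparisons so the operator can
    judge whether exclusion is statistically safe (PI < 1/#comparisons).
    """
    if max_mismatch_loci < 0:
        raise ValueError("max_mismatch_loci must be >= 0")
    a = np.sort(gm.alleles, axis=2)  # unordered genotype comparison
    present = a[:, :, 0] != MISSING
    n = gm.n
    pairs: list[DuplicatePair] = []
    for i, j in itertools.combinations(range(n), 2):
        both = present[i] & present[j]
        compared = int(both.sum())
        if compared == 0:
            continue
        mism = int((a[i, both] != a[j, both]).any(axis=1).sum())
        if mism <= max_mismatch_loci:
            pairs.append(
                DuplicatePair(gm.sample_ids[i], gm.sample_ids[j], mism, compared)
            )
    try:
        _, pi = probability_of_identity(gm)
        n_comparisons = n * (n - 1) // 2
        confident = pi < 1.0 / max(n_comparisons, 1)
        logger.info(
            "overall PI = %.3g over %d pairwise comparisons (confident "
            "duplicate exclusion: %s)",
            pi,
            n_comparisons,
            confident,
        )
    except ValueError:
        pass
    return pairs


def screen_duplicates(
    gm: GenotypeMatrix,
    max_mismatch_loci: int = 0,
    min_loci_typed: int = 1,
) -> tuple[GenotypeMatrix, list[str], list[DuplicatePair]]:
    """Drop failed samples (< ``min_loci_typed`` loci) and duplicates.

    For each duplicate pair the later sample (input order) is removed;
    returns (screened matrix, removed ids, duplicate report).  Near-matches
    at ``max_mismatch_loci + 1`` are also reported for operator review.
    """
    typed = (gm.alleles[:, :, 0] != MISSING).sum(axis=1)
    failed = [s for s, t in zip(gm.sample_ids, typed) if t < min_loci_typed]
    keep = [s for s in gm.sample_ids if s not in set(failed)]
    gm2 = gm.subset(keep)
    pairs = find_duplicates(gm2, max_mismatch_loci)
    near = find_duplicates(gm2, max_mismatch_loci + 1)
    near = [
        p for p in near if p.mismatch_loci == max_mismatch_loci + 1
    ]
    if near:
        logger.info("%d near-match pairs at %d mismatching loci (kept)",
                    len(near), max_mismatch_loci + 1)
    order = {s: i for i, s in enumerate(gm2.sample_ids)}
    removed: set[str] = set()
    for p in sorted(pairs, key=lambda p: (order[p.sample_a], order[p.sample_b])):
        if p.sample_a in removed:
            continue
        removed.add(p.sample_b)
    kept = [s for s in gm2.sample_ids if s not in removed]
    return gm2.subset(kept), failed + sorted(removed, key=order.get), pairs
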