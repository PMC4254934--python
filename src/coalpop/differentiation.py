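"""Pairwise population differentiation with permutation significance.

Sequence statistics (haplotype-frequency FST and ΦST) are computed in the
two-level AMOVA framework from a matrix of squared inter-individual
distances; microsatellite FST is Weir & Cockerham's θ with variance
components summed across loci.  Significance comes from permuting
individuals across the two populations holding sample sizes fixed, with the
+1 correction so a p-value is never exactly zero.  Raw p-values are
reported (no multiple-test correction); a Bonferroni column is emitted in
reports for reference only.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .alignment import hamming_distance_matrix, k2p_distance_matrix
from .datatypes import (
    MISSING,
    GenotypeMatrix,
    HaplotypeTable,
    PopulationPartition,
    SequenceAlignment,
    TestResult,
    as_rng,
)


def amova_fst(d2: np.ndarray, labels: np.ndarray) -> float:
    """Two-level AMOVA fixation index from squared distances.

    sigma^2_among / (sigma^2_among + sigma^2_within) via the standard
    sums-of-squared-deviations decomposition.  Undefined (zero total
    variance) returns 0.  Negative variance components are retained; the
    ratio is floored at -1.
    """
    labels = np.asarray(labels)
    groups = [np.flatnonzero(labels == g) for g in np.unique(labels)]
    n_g = np.array([len(g) for g in groups])
    N, G = int(n_g.sum()), len(groups)
    if G < 2 or (n_g < 2).any():
        raise ValueError("need >= 2 populations with >= 2 members each")
    ssd_total = d2.sum() / (2.0 * N)
    ssd_within = sum(d2[np.ix_(g, g)].sum() / (2.0 * len(g)) for g in groups)
    ssd_among = ssd_total - ssd_within
    sigma_w = ssd_within / (N - G)
    n_prime = (N - (n_g**2).sum() / N) / (G - 1)
    sigma_a = (ssd_among / (G - 1) - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    if denom == 0.0:
        return 0.0
    return float(max(sigma_a / denom, -1.0))


def _expand_haplotype_labels(
    ht: HaplotypeTable, pop_a: str, pop_b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-individuals (haplotype index, population label) for two pops."""
    hap_idx: list[int] = []
    labels: list[int] = []
    for lab, pop in enumerate((pop_a, pop_b)):
        counts = ht.population_counts(pop)
        for h, c in enumerate(counts):
            hap_idx.extend([h] * int(c))
            labels.extend([lab] * int(c))
    return np.array(hap_idx), np.array(labels)


def pairwise_fst_haplotype(ht: HaplotypeTable, pop_a: str, pop_b: str) -> float:
    """AMOVA FST with identity distance (0/1 between distinct haplotypes)."""
    hap_idx, labels = _expand_haplotype_labels(ht, pop_a, pop_b)
    d2 = (hap_idx[:, None] != hap_idx[None, :]).astype(float)
    return amova_fst(d2, labels)


def pairwise_phist(
    aln: SequenceAlignment,
    part: PopulationPartition,
    pop_a: str,
    pop_b: str,
    distance_model: str = "pairwise_differences",
) -> float:
    """AMOVA ΦST from inter-sequence distances.

    ``distance_model``: 'pairwise_differences' (default, the number of
    differing sites) or 'K2P' (multiple-hit corrected).
    """
    ids = part.samples(pop_a) + part.samples(pop_b)
    sub = aln.subset(ids)
    if distance_model == "pairwise_differences":
        d2 = hamming_distance_matrix(sub)
    elif distance_model == "K2P":
        d2 = k2p_distance_matrix(sub)
    else:
        raise ValueError(f"unknown distance model {distance_model!r}")
    labels = np.array([0] * len(part.samples(pop_a)) + [1] * len(part.samples(pop_b)))
    return amova_fst(d2, labels)


def weir_cockerham_components(
    gm: GenotypeMatrix,
    part: PopulationPartition,
    pop_a: str,
    pop_b: str,
) -> tuple[float, float, float]:
    """Summed Weir & Cockerham (1984) variance components (a, b, c).

    Per locus and allele, with r = 2 populations; missing genotypes dropped
    per locus; monomorphic loci contribute nothing.
    """
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    rows = [
        [idx[s] for s in part.samples(p) if s in idx] for p in (pop_a, pop_b)
    ]
    A = B = C = 0.0
    r = 2
    for j in range(gm.n_loci):
        per_pop = []
        for rws in rows:
            geno = gm.alleles[rws, j, :]
            geno = geno[geno[:, 0] != MISSING]
            if geno.shape[0] >= 1:
                per_pop.append(geno)
        if len(per_pop) < 2:
            continue
        sizes = np.unique(np.concatenate([g.ravel() for g in per_pop]))
        if len(sizes) < 2:
            continue
        n_i = np.array([g.shape[0] for g in per_pop], dtype=float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        for allele in sizes:
            p_i = np.array([(g == allele).mean() for g in per_pop])
            h_i = np.array(
                [((g[:, 0] == allele) ^ (g[:, 1] == allele)).mean() for g in per_pop]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (
                nbar
                / nc
                * (
                    s2
                    - 1.0
                    / (nbar - 1)
                    * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
                )
            )
            b = (
                nbar
                / (nbar - 1)
                * (
                    pbar * (1 - pbar)
                    - (r - 1) / r * s2
                    - (2 * nbar - 1) / (4 * nbar) * hbar
                )
            )
            c = hbar / 2.0
            A += a
            B += b
            C += c
    return A, B, C


def pairwise_fst_microsat(
    gm: GenotypeMatrix,
    part: PopulationPartition,
    pop_a: str,
    pop_b: str,
) -> float:
    """Weir & Cockerham θ combined across loci by summing components."""
    A, B, C = weir_cockerham_components(gm, part, pop_a, pop_b)
    denom = A + B + C
    if denom == 0.0:
        raise ValueError("no polymorphic locus shared by the two populations")
    return float(max(A / denom, -1.0))


def permutation_pvalue(
    statistic_fn: Callable[[np.ndarray], float],
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Permute individuals across the two populations (sizes fixed).

    ``statistic_fn`` maps a label vector to the statistic; p = (1 +
    #{perm >= observed}) / (n_perm + 1).  A statistic constant under
    permutation yields p = 1 with a 'degenerate' flag.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    rng = as_rng(seed)
    obs = statistic_fn(labels)
    perm_vals = np.empty(n_perm)
    for b in range(n_perm):
        perm_vals[b] = statistic_fn(rng.permutation(labels))
    flags = []
    if np.allclose(perm_vals, perm_vals[0]) and np.isclose(obs, perm_vals[0]):
        return TestResult(
            name="permutation",
            statistic=float(obs),
            p_value=1.0,
            method="permutation",
            n_reps=n_perm,
            seed=seed,
            flags=["degenerate"],
        )
    p = (1 + int((perm_vals >= obs - 1e-12).sum())) / (n_perm + 1)
    return TestResult(
        name="permutation",
        statistic=float(obs),
        p_value=p,
        method="permutation",
        n_reps=n_perm,
        seed=seed,
        flags=flags,
    )


def phist_permutation_test(
    d2: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    name: str = "PhiST",
) -> TestResult:
    """Vectorised two-population AMOVA permutation test.

    Equivalent to :func:`permutation_pvalue` over :func:`amova_fst` but
    computes all permuted statistics with matrix algebra, which keeps the
    paper-scale 10,000-permutation default cheap.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("exactly two populations required")
    z_obs = (labels == uniq[0]).astype(float)
    n = labels.size
    n1 = int(z_obs.sum())
    n2 = n - n1
    ssd_total = d2.sum() / (2.0 * n)

    def _stats(Z: np.ndarray) -> np.ndarray:
        within_a = np.einsum("bi,ij,bj->b", Z, d2, Z) / (2.0 * n1)
        W = 1.0 - Z
        within_b = np.einsum("bi,ij,bj->b", W, d2, W) / (2.0 * n2)
        ssd_within = within_a + within_b
        ssd_among = ssd_total - ssd_within
        sigma_w = ssd_within / (n - 2)
        n_prime = (n - (n1**2 + n2**2) / n) / 1.0
        sigma_a = (ssd_among - sigma_w) / n_prime
        denom = sigma_a + sigma_w
        out = np.zeros_like(denom)
        nz = denom != 0
        out[nz] = sigma_a[nz] / denom[nz]
        return np.maximum(out, -1.0)

    obs = float(_stats(z_obs[None, :])[0])
    rng = as_rng(seed)
    u = rng.random((n_perm, n))
    order = np.argsort(u, axis=1)
    Z = np.zeros((n_perm, n))
    np.put_along_axis(Z, order[:, :n1], 1.0, axis=1)
    perm_vals = _stats(Z)
    p = (1 + int((perm_vals >= obs - 1e-12).sum())) / (n_perm + 1)
    return TestResult(
        name=name,
        statistic=obs,
        p_value=p,
        method="permutation",
        n_reps=n_perm,
        seed=seed,
    )


def shared_haplotype_matrix(
    ht: HaplotypeTable,
) -> tuple[np.ndarray, dict[str, int]]:
    """Counts of haplotypes shared between population pairs, plus private
    haplotype counts per population."""
    if len(ht.populations) < 2:
        raise ValueError("need >= 2 populations")
    present = ht.counts > 0  # (H, P)
    shared = (present[:, :, None] & present[:, None, :]).sum(axis=0)
    private = {}
    for j, pop in enumerate(ht.populations):
        only_here = present[:, j] & (present.sum(axis=1) == 1)
        private[pop] = int(only_here.sum())
    return shared, private
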