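"""Within-population diversity and locus-quality tests.

Sequence side: haplotype diversity Hd (with Nei's sampling variance) and the
mean number of pairwise nucleotide differences k (with Tajima's total
variance).  Microsatellite side: per-locus allele counts K, observed and
unbiased expected heterozygosity (Ho, He), an exact/Monte-Carlo HWE
probability test, and a genotypic permutation test of linkage
disequilibrium using the log-likelihood G statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import combine_pvalues as _combine

from .alignment import hamming_distance_matrix
from .datatypes import (
    MISSING,
    GenotypeMatrix,
    HaplotypeTable,
    SequenceAlignment,
    TestResult,
    as_rng,
    warn,
)


def haplotype_diversity(
    ht: HaplotypeTable, population: str
) -> tuple[float, float]:
    """Hd = n/(n-1) (1 - sum p_i^2) with Nei (1987) sampling variance.

    Returns (Hd, sd).
    """
    counts = ht.population_counts(population)
    counts = counts[counts > 0]
    n = int(counts.sum())
    if n < 2:
        raise ValueError(f"need n >= 2 in population {population}")
    p = counts / n
    sum2 = float((p**2).sum())
    sum3 = float((p**3).sum())
    hd = n / (n - 1) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1))
        * (2.0 * (n - 2) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return hd, float(np.sqrt(max(var, 0.0)))


def mean_pairwise_differences(aln: SequenceAlignment) -> tuple[float, float]:
    """k = mean Hamming distance over all pairs (complete deletion).

    The standard deviation uses Tajima's (1983) total (stochastic +
    sampling) variance under neutrality,
    V(k) = b1 k + b2 k^2 with b1 = (n+1)/(3(n-1)) and
    b2 = 2(n^2+n+3)/(9n(n-1)).
    """
    n = aln.n
    if n < 2:
        raise ValueError("need >= 2 sequences")
    d = hamming_distance_matrix(aln)
    iu = np.triu_indices(n, 1)
    k = float(d[iu].mean())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    var = b1 * k + b2 * k**2
    return k, float(np.sqrt(max(var, 0.0)))


def locus_summaries(gm: GenotypeMatrix, sample_ids=None) -> pd.DataFrame:
    """Per-locus K (allele count), Ho, and unbiased He (Nei 1978).

    He = 2n/(2n-1) (1 - sum p_i^2) with n the number of genotyped
    individuals.  Entirely-missing loci are excluded with a warning.
    """
    sub = gm if sample_ids is None else gm.subset(list(sample_ids))
    rows = {}
    for j, name in enumerate(sub.locus_names):
        mask = sub.genotyped_at(j)
        geno = sub.alleles[mask, j, :]
        n = geno.shape[0]
        if n < 2:
            warn(f"locus {name}: <2 genotyped individuals; excluded")
            continue
        sizes, counts = np.unique(geno, return_counts=True)
        p = counts / counts.sum()
        ho = float((geno[:, 0] != geno[:, 1]).mean())
        he = float(2 * n / (2 * n - 1) * (1.0 - (p**2).sum()))
        rows[name] = {"K": len(sizes), "Ho": ho, "He": he, "n": n}
    if not rows:
        raise ValueError("no usable locus")
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# HWE probability test
# ---------------------------------------------------------------------------


def _log_array_weight(het: np.ndarray, log_fact_counts: np.ndarray) -> np.ndarray:
    """Varying part of the conditional genotype-array log-probability.

    Conditional on the allele counts, P(array) is proportional to
    2^h / prod(genotype counts!), h = number of heterozygotes.
    """
    return het * np.log(2.0) - log_fact_counts


def _hwe_exact_diallelic(n11: int, n12: int, n22: int) -> float:
    """Complete enumeration of diallelic genotype arrays (Levene/Haldane).

    p = sum of conditional probabilities of arrays no more probable than the
    observed one.
    """
    n = n11 + n12 + n22
    n1 = 2 * n11 + n12

    def logp(h: int) -> float:
        a = (n1 - h) // 2
        b = (2 * n - n1 - h) // 2
        return (
            h * np.log(2.0)
            - gammaln(a + 1)
            - gammaln(h + 1)
            - gammaln(b + 1)
        )

    hs = np.arange(n1 % 2, min(n1, 2 * n - n1) + 1, 2)
    logps = np.array([logp(int(h)) for h in hs])
    logps -= logps.max()
    probs = np.exp(logps)
    probs /= probs.sum()
    obs = probs[np.flatnonzero(hs == n12)[0]]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def hwe_probability_test(
    gm: GenotypeMatrix,
    locus: str,
    sample_ids=None,
    reps: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Exact conditional probability test of Hardy-Weinberg equilibrium.

    Diallelic loci are handled by complete enumeration; loci with more
    alleles use a Monte-Carlo randomisation of the allele array (Guo &
    Thompson's conditional test): p is the fraction of genotype arrays, at
    fixed allele counts, whose conditional probability is <= the observed
    one (ties counted as extreme, +1 correction).
    """
    sub = gm if sample_ids is None else gm.subset(list(sample_ids))
    j = sub.locus_names.index(locus)
    geno = sub.alleles[sub.genotyped_at(j), j, :]
    n = geno.shape[0]
    if n < 2:
        raise ValueError(f"locus {locus}: need >= 2 genotyped individuals")
    sizes = np.unique(geno)
    k = len(sizes)
    if k == 1:
        return TestResult(
            name=f"HWE[{locus}]",
            statistic=float("nan"),
            p_value=1.0,
            method="exact",
            flags=["degenerate"],
        )
    code = {s: i for i, s in enumerate(sizes)}
    g = np.vectorize(code.get)(geno)
    if k == 2:
        n12 = int((g[:, 0] != g[:, 1]).sum())
        n11 = int(((g[:, 0] == 0) & (g[:, 1] == 0)).sum())
        n22 = n - n11 - n12
        p = _hwe_exact_diallelic(n11, n12, n22)
        return TestResult(
            name=f"HWE[{locus}]",
            statistic=float(n12) / n,
            p_value=p,
            method="exact",
            extras={"n": n, "alleles": k},
        )
    # Monte-Carlo: shuffle the flat allele array, re-pair into genotypes
    rng = as_rng(seed)
    flat = np.sort(g, axis=1)
    obs_lw = _observed_weight(flat, k, n)
    pool = g.reshape(-1)
    u = rng.random((reps, pool.size))
    perm = np.argsort(u, axis=1)
    shuffled = pool[perm].reshape(reps, n, 2)
    shuffled.sort(axis=2)
    lw = _batch_weights(shuffled, k, n)
    hits = int((lw <= obs_lw + 1e-9).sum())
    return TestResult(
        name=f"HWE[{locus}]",
        statistic=float((flat[:, 0] != flat[:, 1]).mean()),
        p_value=(1 + hits) / (reps + 1),
        method="permutation",
        n_reps=reps,
        seed=seed,
        extras={"n": n, "alleles": k},
    )


def _observed_weight(sorted_geno: np.ndarray, k: int, n: int) -> float:
    codes = sorted_geno[:, 0] * k + sorted_geno[:, 1]
    counts = np.bincount(codes, minlength=k * k)
    het = int((sorted_geno[:, 0] != sorted_geno[:, 1]).sum())
    return float(het * np.log(2.0) - gammaln(counts + 1).sum())


def _batch_weights(sorted_geno: np.ndarray, k: int, n: int) -> np.ndarray:
    reps = sorted_geno.shape[0]
    codes = sorted_geno[..., 0] * k + sorted_geno[..., 1]
    offset = (np.arange(reps) * (k * k))[:, None]
    counts = np.bincount((codes + offset).ravel(), minlength=reps * k * k)
    counts = counts.reshape(reps, k * k)
    het = (sorted_geno[..., 0] != sorted_geno[..., 1]).sum(axis=1)
    return het * np.log(2.0) - gammaln(counts + 1).sum(axis=1)


# ---------------------------------------------------------------------------
# Linkage disequilibrium test
# ---------------------------------------------------------------------------


def linkage_disequilibrium_test(
    gm: GenotypeMatrix,
    locus_a: str,
    locus_b: str,
    sample_ids=None,
    reps: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Genotypic contingency-table permutation test for LD.

    Statistic: log-likelihood G on the two-locus genotype table.  One
    locus's genotypes are shuffled across individuals; p = (1 + #{G_perm >=
    G_obs}) / (reps + 1).  With the margins fixed by the shuffle, only
    sum O log O varies, which is what is computed.
    """
    sub = gm if sample_ids is None else gm.subset(list(sample_ids))
    ja = sub.locus_names.index(locus_a)
    jb = sub.locus_names.index(locus_b)
    both = sub.genotyped_at(ja) & sub.genotyped_at(jb)
    if int(both.sum()) < 5:
        return TestResult(
            name=f"LD[{locus_a},{locus_b}]",
            statistic=float("nan"),
            p_value=None,
            method="permutation",
            flags=["not testable"],
        )
    ga = np.sort(sub.alleles[both, ja, :], axis=1)
    gb = np.sort(sub.alleles[both, jb, :], axis=1)
    codes_a = _genotype_codes(ga)
    codes_b = _genotype_codes(gb)
    ka, kb = codes_a.max() + 1, codes_b.max() + 1
    if ka < 2 or kb < 2:
        return TestResult(
            name=f"LD[{locus_a},{locus_b}]",
            statistic=float("nan"),
            p_value=None,
            method="permutation",
            flags=["not testable"],
        )
    n = codes_a.size

    def _sum_o_log_o(cb: np.ndarray) -> np.ndarray:
        joint = codes_a[None, :] * kb + cb
        reps_ = joint.shape[0]
        offset = (np.arange(reps_) * (ka * kb))[:, None]
        counts = np.bincount((joint + offset).ravel(), minlength=reps_ * ka * kb)
        counts = counts.reshape(reps_, ka * kb).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            olo = np.where(counts > 0, counts * np.log(counts), 0.0)
        return olo.sum(axis=1)

    obs = _sum_o_log_o(codes_b[None, :])[0]
    rng = as_rng(seed)
    u = rng.random((reps, n))
    perms = np.argsort(u, axis=1)
    perm_vals = _sum_o_log_o(codes_b[perms])
    hits = int((perm_vals >= obs - 1e-9).sum())
    # report the full G for the observed table
    ra = np.bincount(codes_a, minlength=ka).astype(float)
    rb = np.bincount(codes_b, minlength=kb).astype(float)
    g_obs = 2.0 * (
        obs
        - np.where(ra > 0, ra * np.log(ra), 0.0).sum()
        - np.where(rb > 0, rb * np.log(rb), 0.0).sum()
        + n * np.log(n)
    )
    return TestResult(
        name=f"LD[{locus_a},{locus_b}]",
        statistic=float(g_obs),
        p_value=(1 + hits) / (reps + 1),
        method="permutation",
        n_reps=reps,
        seed=seed,
        extras={"n": n},
    )


def _genotype_codes(sorted_geno: np.ndarray) -> np.ndarray:
    pairs = [tuple(row) for row in sorted_geno]
    uniq = {p: i for i, p in enumerate(dict.fromkeys(pairs))}
    return np.array([uniq[p] for p in pairs])


def combine_across_loci(p_values: list[float]) -> float:
    """Fisher's method for an across-loci p-value (combination method is a
    package choice; flagged in reports)."""
    stat, p = _combine([max(p, 1e-300) for p in p_values], method="fisher")
    return float(p)
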