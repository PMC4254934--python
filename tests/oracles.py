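"""Independent brute-force reference implementations.

Deliberately naive (explicit loops, direct textbook formulas, no shared
code with the package) so they can serve as oracles for the vectorised
library implementations.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_pairwise_diffs(seqs: list[str]) -> float:
    """Mean Hamming distance over all pairs (no missing data expected)."""
    n = len(seqs)
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (n * (n - 1) / 2)


def naive_segregating_sites(seqs: list[str]) -> int:
    count = 0
    for col in zip(*seqs):
        states = {c for c in col if c not in "-N"}
        if len(states) >= 2:
            count += 1
    return count


def naive_haplotype_diversity(counts: list[int]) -> float:
    n = sum(counts)
    sum_p2 = sum((c / n) ** 2 for c in counts)
    return n / (n - 1) * (1 - sum_p2)


def naive_tajimas_d(seqs: list[str]) -> float:
    n = len(seqs)
    S = naive_segregating_sites(seqs)
    k = naive_pairwise_diffs(seqs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def naive_r2(seqs: list[str]) -> float:
    """R2 with U_i = #sites where sequence i's state occurs exactly once."""
    n = len(seqs)
    S = naive_segregating_sites(seqs)
    k = naive_pairwise_diffs(seqs)
    u = np.zeros(n)
    for col in zip(*seqs):
        counts: dict[str, int] = {}
        for c in col:
            counts[c] = counts.get(c, 0) + 1
        if len(counts) < 2:
            continue
        for i, c in enumerate(col):
            if counts[c] == 1:
                u[i] += 1
    return float(np.sqrt(np.mean((u - k / 2) ** 2)) / S)


def naive_raggedness(seqs: list[str]) -> float:
    n = len(seqs)
    diffs = []
    for i, j in itertools.combinations(range(n), 2):
        diffs.append(sum(a != b for a, b in zip(seqs[i], seqs[j])))
    dmax = max(diffs)
    freqs = [diffs.count(d) / len(diffs) for d in range(dmax + 1)]
    return sum((freqs[i] - freqs[i - 1]) ** 2 for i in range(1, dmax + 1))


def naive_amova_fst(d2: np.ndarray, labels: np.ndarray) -> float:
    """Direct sums-of-squares two-level AMOVA decomposition."""
    N = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            ss_total += d2[i, j]
    ss_total /= N
    ss_within = 0.0
    sizes = []
    for g in groups:
        members = [i for i in range(N) if labels[i] == g]
        sizes.append(len(members))
        s = 0.0
        for a, b in itertools.combinations(members, 2):
            s += d2[a, b]
        ss_within += s / len(members)
    ss_among = ss_total - ss_within
    G = len(groups)
    sigma_w = ss_within / (N - G)
    n_prime = (N - sum(m**2 for m in sizes) / N) / (G - 1)
    sigma_a = (ss_among / (G - 1) - sigma_w) / n_prime
    if sigma_a + sigma_w == 0:
        return 0.0
    return max(sigma_a / (sigma_a + sigma_w), -1.0)


def naive_wc_theta(genos_by_pop: list[np.ndarray]) -> float:
    """Weir & Cockerham theta for r populations, one or more loci.

    genos_by_pop: per population an (n_i, n_loci, 2) array; missing rows
    must already be dropped per locus by the caller (pass clean data).
    """
    r = len(genos_by_pop)
    n_loci = genos_by_pop[0].shape[1]
    num = den = 0.0
    for locus in range(n_loci):
        per_pop = [g[:, locus, :] for g in genos_by_pop]
        alleles = sorted(set(np.concatenate(per_pop).ravel().tolist()))
        if len(alleles) < 2:
            continue
        n_i = [p.shape[0] for p in per_pop]
        nbar = sum(n_i) / r
        nc = (r * nbar - sum(x**2 for x in n_i) / (r * nbar)) / (r - 1)
        for A in alleles:
            p_i = [np.mean(p == A) for p in per_pop]
            h_i = [
                np.mean((p[:, 0] == A) != (p[:, 1] == A)) for p in per_pop
            ]
            pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / (
                (r - 1) * nbar
            )
            hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2
                - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            num += a
            den += a + b + c
    return num / den


def naive_pi_locus(freqs: list[float]) -> float:
    """Probability of identity for one locus by exhaustive genotype-pair
    enumeration under HWE."""
    k = len(freqs)
    pi = 0.0
    for i in range(k):
        for j in range(i, k):
            g = (
                freqs[i] ** 2
                if i == j
                else 2 * freqs[i] * freqs[j]
            )
            pi += g**2
    return pi
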