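"""Simulation studies: type-I calibration, bottleneck power, parameter
recovery.

These are the package's own validation experiments, run at study-scale
conditions (n = 47 individuals, 11 microsatellite loci, 486-bp sequences)
with replicate counts sized so the full battery completes in minutes on
one core.  Each function takes one seed and returns plain dictionaries of
rates and estimates.
"""

from __future__ import annotations

import warnings

import numpy as np

from .alignment import hamming_distance_matrix
from .bottleneck import (
    CONSERVATIVE_TPM,
    REALISTIC_TPM,
    TwoPhaseModel,
    het_excess_test,
    m_ratio,
    simulate_mc,
)
from .datatypes import as_rng, spawn_seeds
from .differentiation import phist_permutation_test
from .diversity import hwe_probability_test, linkage_disequilibrium_test
from .ne import het_excess_nb, ld_ne
from .neutrality import (
    _stat_from_sim,
    r2_statistic,
    simulate_fixed_s,
    tajimas_d,
)
from .synth import (
    CoalescentScenario,
    msat_locus_equilibrium,
    pair_copies_to_genotypes,
    progeny_of_breeders,
    simulate_bottleneck_microsats,
    simulate_microsat_dataset,
    simulate_sequences_theta,
    wright_fisher_genotypes,
)

#: study-scale conditions used by every experiment
N_IND = 47
N_LOCI = 11
SEQ_LEN = 486
MSAT_THETA = 1.0
SEQ_THETA = 5.0
ALPHA = 0.05


def binomial_99_ci(alpha: float, n: int) -> tuple[float, float]:
    """99% normal-approximation band for a rejection rate at nominal alpha."""
    half = 2.576 * np.sqrt(alpha * (1 - alpha) / n)
    return alpha - half, alpha + half


# ---------------------------------------------------------------------------
# Type-I calibration under equilibrium (null) simulation
# ---------------------------------------------------------------------------


def calibrate_hwe(n_datasets: int = 500, reps: int = 1000, seed: int = 0) -> float:
    """Rejection rate of the HWE probability test on HWE-true samples."""
    rng = as_rng(seed)
    rej = 0
    used = 0
    for i in range(n_datasets):
        sizes = msat_locus_equilibrium(2 * N_IND, MSAT_THETA, 0.9, 3.5, rng)
        if len(np.unique(sizes)) < 2:
            continue
        gm = pair_copies_to_genotypes([sizes])
        tr = hwe_probability_test(
            gm, gm.locus_names[0], reps=reps, seed=int(rng.integers(2**31 - 1))
        )
        used += 1
        if tr.p_value is not None and tr.p_value <= ALPHA:
            rej += 1
    return rej / used


def calibrate_ld(n_datasets: int = 500, reps: int = 1000, seed: int = 0) -> float:
    """Rejection rate of the LD permutation test on independent loci."""
    rng = as_rng(seed)
    rej = 0
    used = 0
    for i in range(n_datasets):
        a = msat_locus_equilibrium(2 * N_IND, MSAT_THETA, 0.9, 3.5, rng)
        b = msat_locus_equilibrium(2 * N_IND, MSAT_THETA, 0.9, 3.5, rng)
        if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
            continue
        gm = pair_copies_to_genotypes([a, b])
        tr = linkage_disequilibrium_test(
            gm,
            gm.locus_names[0],
            gm.locus_names[1],
            reps=reps,
            seed=int(rng.integers(2**31 - 1)),
        )
        if tr.p_value is None:
            continue
        used += 1
        if tr.p_value <= ALPHA:
            rej += 1
    return rej / used


def calibrate_het_excess(
    n_datasets: int = 500, null_reps: int = 300, seed: int = 0
) -> float:
    """Rejection rate of the heterozygosity-excess test at equilibrium.

    Data and nulls both use the conservative TPM, so the test sees a
    correctly specified model; conditional nulls are cached by observed
    allele count.
    """
    rng = as_rng(seed)
    tpm = TwoPhaseModel(**CONSERVATIVE_TPM)
    cache: dict = {}
    rej = 0
    used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_datasets):
            gm = simulate_microsat_dataset(
                N_IND, N_LOCI, MSAT_THETA, tpm.ps, tpm.delta_g, rng
            )
            try:
                tr = het_excess_test(
                    gm,
                    tpm,
                    reps=null_reps,
                    seed=int(rng.integers(2**31 - 1)),
                    null_cache=cache,
                )
            except (ValueError, RuntimeError):
                continue
            used += 1
            if tr.p_value <= ALPHA:
                rej += 1
    return rej / used


def _fixed_s_null_both(
    n: int, S: int, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Joint null samples of D and R2 from shared fixed-S replicates."""
    d = np.empty(reps)
    r2 = np.empty(reps)
    for b in range(reps):
        X = simulate_fixed_s(n, S, rng)
        d[b] = _stat_from_sim(X, "D")
        r2[b] = _stat_from_sim(X, "R2")
    return d, r2


def calibrate_d_r2(
    n_datasets: int = 500, null_reps: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Upper-tail rejection rates of Tajima's D and R2 at equilibrium."""
    rng = as_rng(seed)
    cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    rej_d = rej_r2 = used = 0
    for i in range(n_datasets):
        aln = simulate_sequences_theta(N_IND, SEQ_THETA, SEQ_LEN, rng)
        d = tajimas_d(aln)
        if d.p_value is None and "undefined: S=0" in d.flags:
            continue
        S = d.extras["S"]
        if S not in cache:
            cache[S] = _fixed_s_null_both(N_IND, S, null_reps, rng)
        null_d, null_r2 = cache[S]
        used += 1
        p_d = (1 + (null_d >= d.statistic - 1e-12).sum()) / (null_reps + 1)
        r2 = r2_statistic(aln)
        p_r2 = (1 + (null_r2 >= r2.statistic - 1e-12).sum()) / (null_reps + 1)
        rej_d += p_d <= ALPHA
        rej_r2 += p_r2 <= ALPHA
    return rej_d / used, rej_r2 / used


def calibrate_perm_fst(
    n_datasets: int = 500, n_perm: int = 1000, seed: int = 0
) -> float:
    """Rejection rate of the PhiST permutation test on arbitrary splits of a
    single panmictic population."""
    rng = as_rng(seed)
    labels = np.array([0] * (N_IND // 2) + [1] * (N_IND - N_IND // 2))
    rej = 0
    for i in range(n_datasets):
        aln = simulate_sequences_theta(N_IND, SEQ_THETA, SEQ_LEN, rng)
        d2 = hamming_distance_matrix(aln)
        tr = phist_permutation_test(
            d2, labels, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        if tr.p_value <= ALPHA:
            rej += 1
    return rej / n_datasets


def calibration_suite(seed: int = 0, n_datasets: int = 500) -> dict:
    """All six type-I calibration rates at nominal alpha = 0.05."""
    seeds = spawn_seeds(seed, 5)
    d_rate, r2_rate = calibrate_d_r2(n_datasets, seed=seeds[3])
    return {
        "hwe": calibrate_hwe(n_datasets, seed=seeds[0]),
        "ld": calibrate_ld(n_datasets, seed=seeds[1]),
        "het_excess": calibrate_het_excess(n_datasets, seed=seeds[2]),
        "tajimas_d": d_rate,
        "r2": r2_rate,
        "perm_fst": calibrate_perm_fst(n_datasets, seed=seeds[4]),
        "n_datasets": n_datasets,
        "band_99": binomial_99_ci(ALPHA, n_datasets),
    }


# ---------------------------------------------------------------------------
# Bottleneck power / diagnostics
# ---------------------------------------------------------------------------

BOTTLENECK_SCENARIO = CoalescentScenario(
    kind="bottleneck", ne_anc=5000, ne_post=50, t_bottleneck=3
)
MSAT_MU = 5e-4
#: matched equilibrium diversity: 4 * ne_anc * mu
EQ_THETA = 4 * 5000 * MSAT_MU


def m_ratio_contrast(
    n_datasets: int = 120, seed: int = 0
) -> dict:
    """Mean M-ratio, equilibrium vs recent bottleneck (paired replicates)."""
    rng = as_rng(seed)
    tpm = REALISTIC_TPM
    eq, bn = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_datasets):
            gm_eq = simulate_microsat_dataset(
                N_IND, N_LOCI, EQ_THETA, tpm["ps"], tpm["delta_g"], rng
            )
            gm_bn = simulate_bottleneck_microsats(
                N_IND,
                N_LOCI,
                BOTTLENECK_SCENARIO,
                MSAT_MU,
                tpm["ps"],
                tpm["delta_g"],
                rng,
            )
            eq.append(m_ratio(gm_eq).mean)
            bn.append(m_ratio(gm_bn).mean)
    return {
        "mean_m_equilibrium": float(np.mean(eq)),
        "mean_m_bottleneck": float(np.mean(bn)),
        "n_datasets": n_datasets,
    }


def het_excess_power(
    n_datasets: int = 80, null_reps: int = 300, seed: int = 0
) -> float:
    """Power of the heterozygosity-excess test under the bottleneck."""
    rng = as_rng(seed)
    tpm = TwoPhaseModel(**CONSERVATIVE_TPM)
    cache: dict = {}
    rej = used = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_datasets):
            gm = simulate_bottleneck_microsats(
                N_IND,
                N_LOCI,
                BOTTLENECK_SCENARIO,
                MSAT_MU,
                tpm.ps,
                tpm.delta_g,
                rng,
            )
            try:
                tr = het_excess_test(
                    gm,
                    tpm,
                    reps=null_reps,
                    seed=int(rng.integers(2**31 - 1)),
                    null_cache=cache,
                )
            except (ValueError, RuntimeError):
                continue
            used += 1
            rej += tr.p_value <= ALPHA
    return rej / used


def mc_curves(reps: int = 300, seed: int = 0) -> dict:
    """Mc(theta) for the conservative and realistic TPM parameter sets."""
    out = {}
    for label, kw in (("conservative", CONSERVATIVE_TPM), ("realistic", REALISTIC_TPM)):
        res = simulate_mc(
            2 * N_IND, N_LOCI, TwoPhaseModel(**kw), reps=reps, seed=seed
        )
        out[label] = {
            "theta": res.theta_grid.tolist(),
            "mc": res.mc.tolist(),
        }
    return out


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------


def ld_ne_recovery(
    true_ne: int = 100, n_replicates: int = 200, seed: int = 0
) -> dict:
    """Median LD-Ne and CI coverage over forward Wright-Fisher replicates."""
    seeds = spawn_seeds(seed, n_replicates)
    ests = []
    cover = 0
    for s in seeds:
        gm = wright_fisher_genotypes(
            ne=true_ne,
            n_loci=N_LOCI,
            n_generations=10,
            n_alleles=8,
            sample_size=N_IND,
            seed=s,
        )
        e = ld_ne(gm, pcrit=0.02, seed=s)
        ests.append(e.estimate)
        if e.ci_low <= true_ne <= e.ci_high:
            cover += 1
    ests = np.array(ests)
    return {
        "true_ne": true_ne,
        "median": float(np.median(ests)),
        "ci_coverage": cover / n_replicates,
        "n_replicates": n_replicates,
    }


def nb_ordering(
    breeder_numbers=(2, 10, 50), n_replicates: int = 40, seed: int = 0
) -> dict:
    """Median heterozygote-excess Nb for increasing true breeder numbers."""
    rng = as_rng(seed)
    medians = {}
    for nb in breeder_numbers:
        vals = []
        for _ in range(n_replicates):
            gm = progeny_of_breeders(
                nb, N_LOCI, 8, N_IND, seed=int(rng.integers(2**31 - 1))
            )
            vals.append(het_excess_nb(gm).estimate)
        medians[nb] = float(np.median(vals))
    return {"medians": medians, "n_replicates": n_replicates}


def watterson_check(
    n: int = 10, theta: float = 5.0, reps: int = 10_000, seed: int = 0
) -> dict:
    """E[S] against the Watterson closed form theta * sum_{i<n} 1/i."""
    from .alignment import segregating_sites

    rng = as_rng(seed)
    L = 400
    s_vals = np.empty(reps)
    for b in range(reps):
        aln = simulate_sequences_theta(n, theta, L, rng)
        s_vals[b], _ = segregating_sites(aln)
    expected = theta * sum(1.0 / i for i in range(1, n))
    return {
        "mean_S": float(s_vals.mean()),
        "expected": expected,
        "se": float(s_vals.std(ddof=1) / np.sqrt(reps)),
        "reps": reps,
    }
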