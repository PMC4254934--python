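"""Coalescent synthetic-data engine.

Simulates Kingman genealogies under piecewise-constant demographies
(constant size, bottleneck, two-population split with migration), drops
mutations on them under a finite/infinite-sites sequence model or the
two-phase microsatellite model (TPM), and builds the ASHW-like fixture: a
synthetic stand-in, constructed to the structural counts of the study
population (47 individuals, 7 mtDNA haplotypes over 24 polymorphic sites in
486 bp, 11 microsatellite loci with 3-12 alleles), not a reproduction of
the real genotypes.

Conventions: coalescence rate is 1/(2Ne) per lineage pair per generation;
diploid loci are simulated with 2x gene copies and consecutive copies are
paired into individuals.  Allele sizes are repeat units with a reflecting
boundary at 2 repeats.  All entry points take an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import (
    MISSING,
    GenotypeMatrix,
    PopulationPartition,
    SequenceAlignment,
    as_rng,
)

_BASES = np.array([b"A", b"G", b"C", b"T"])  # purines first: transitions 0<->1, 2<->3


@dataclass
class CoalescentScenario:
    """Demographic model for genealogy simulation.

    kind='constant': ne.
    kind='bottleneck': ne_post (current), ne_anc (pre-crash), t_bottleneck
    generations ago.
    kind='split_migration': two demes of size ne_a / ne_b exchanging a
    fraction m of lineages per generation, merging into an ancestral
    population of size ne_a at t_split generations ago.
    """

    kind: str
    ne: float | None = None
    ne_anc: float | None = None
    ne_post: float | None = None
    t_bottleneck: float | None = None
    ne_a: float | None = None
    ne_b: float | None = None
    t_split: float | None = None
    m: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "bottleneck", "split_migration"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.kind == "constant" and not (self.ne and self.ne > 0):
            raise ValueError("constant scenario requires ne > 0")
        if self.kind == "bottleneck":
            for v in (self.ne_anc, self.ne_post, self.t_bottleneck):
                if not (v and v > 0):
                    raise ValueError("bottleneck requires ne_anc, ne_post, t > 0")
        if self.kind == "split_migration":
            for v in (self.ne_a, self.ne_b, self.t_split):
                if not (v and v > 0):
                    raise ValueError("split requires ne_a, ne_b, t_split > 0")
            if not (0 <= self.m < 1):
                raise ValueError("m must be in [0, 1)")


@dataclass
class Tree:
    """Binary genealogy: nodes 0..n-1 are leaves; root has parent -1.

    ``time`` is in generations (or coalescent units for unit trees); leaves
    sit at time 0.
    """

    n_leaves: int
    parent: np.ndarray
    time: np.ndarray
    leaf_population: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (root gets 0)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return bl

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.time.max())

    def leaf_matrix(self) -> np.ndarray:
        """(n_nodes, n_leaves) bool: leaves descending from each node."""
        n = self.n_leaves
        M = np.zeros((self.n_nodes, n), dtype=bool)
        M[np.arange(n), np.arange(n)] = True
        order = np.argsort(self.time[n:]) + n  # internal nodes, oldest last
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for node in range(self.n_nodes):
            if self.parent[node] >= 0:
                children[self.parent[node]].append(node)
        for node in order:
            for c in children[node]:
                M[node] |= M[c]
        return M


def _ne_at(scenario: CoalescentScenario, t: float) -> float:
    if scenario.kind == "constant":
        return scenario.ne
    if scenario.kind == "bottleneck":
        return scenario.ne_post if t < scenario.t_bottleneck else scenario.ne_anc
    raise AssertionError


def _next_boundary(scenario: CoalescentScenario, t: float) -> float:
    if scenario.kind == "bottleneck" and t < scenario.t_bottleneck:
        return scenario.t_bottleneck
    return np.inf


def simulate_genealogy(
    n: int, scenario: CoalescentScenario, seed: int | np.random.Generator | None
) -> Tree:
    """Random genealogy of ``n`` gene copies under the scenario.

    Deterministic under a fixed seed.  For diploid loci pass 2x the number
    of individuals.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = as_rng(seed)
    if scenario.kind == "split_migration":
        return _simulate_split(n, scenario, rng)
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        while True:
            ne = _ne_at(scenario, t)
            rate = k * (k - 1) / 2.0 / (2.0 * ne)
            w = rng.exponential(1.0 / rate)
            boundary = _next_boundary(scenario, t)
            if t + w < boundary:
                t += w
                break
            t = boundary
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(n_leaves=n, parent=parent, time=time)


def _simulate_split(
    n: int, scenario: CoalescentScenario, rng: np.random.Generator
) -> Tree:
    """Structured coalescent for two demes with symmetric migration.

    Half the sample starts in each deme (n even) unless overridden by
    :func:`simulate_split_sample`.  Backward migration rate per lineage is
    m per generation; after t_split all lineages sit in the ancestral
    population of size ne_a.
    """
    demes = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return _split_from_demes(n, demes, scenario, rng)


def simulate_split_sample(
    n_a: int,
    n_b: int,
    scenario: CoalescentScenario,
    seed: int | np.random.Generator | None,
) -> Tree:
    """Split-scenario genealogy with explicit per-deme sample sizes."""
    rng = as_rng(seed)
    demes = np.array([0] * n_a + [1] * n_b)
    return _split_from_demes(n_a + n_b, demes, scenario, rng)


def _split_from_demes(
    n: int, leaf_demes: np.ndarray, scenario: CoalescentScenario, rng
) -> Tree:
    parent = np.full(2 * n - 1, -1, dtype=int)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    deme = {i: int(leaf_demes[i]) for i in range(n)}
    sizes = (scenario.ne_a, scenario.ne_b)
    t = 0.0
    nxt = n
    merged = False
    while len(active) > 1:
        if not merged and t >= scenario.t_split:
            merged = True
            for x in active:
                deme[x] = 0
        if merged:
            k = len(active)
            rate = k * (k - 1) / 2.0 / (2.0 * scenario.ne_a)
            t += rng.exponential(1.0 / rate)
            pool = active
        else:
            in_deme = [[x for x in active if deme[x] == d] for d in (0, 1)]
            k_d = [len(g) for g in in_deme]
            coal_rates = [
                k_d[d] * (k_d[d] - 1) / 2.0 / (2.0 * sizes[d]) for d in (0, 1)
            ]
            mig_rate = scenario.m * len(active)
            total = coal_rates[0] + coal_rates[1] + mig_rate
            if total == 0:
                t = scenario.t_split
                continue
            w = rng.exponential(1.0 / total)
            if t + w >= scenario.t_split:
                t = scenario.t_split
                continue
            t += w
            u = rng.random() * total
            if u < mig_rate:
                x = active[rng.integers(len(active))]
                deme[x] = 1 - deme[x]
                continue
            d = 0 if u < mig_rate + coal_rates[0] else 1
            pool = in_deme[d]
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        deme[nxt] = deme[a]
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return Tree(n_leaves=n, parent=parent, time=time, leaf_population=leaf_demes)


# ---------------------------------------------------------------------------
# Sequence mutation
# ---------------------------------------------------------------------------


@dataclass
class SequenceMutationModel:
    """Per-site mutation model for sequence simulation.

    mode='infinite_sites': each mutation hits a fresh site (error if more
    mutations than sites).  mode='k2p': finite sites, transition:transversion
    rate ratio kappa; transition probability per mutation is kappa/(kappa+2).
    """

    mu_per_site: float
    mode: str = "infinite_sites"
    kappa: float = 2.0

    def __post_init__(self) -> None:
        if self.mu_per_site < 0:
            raise ValueError("negative mutation rate")
        if self.mode not in ("infinite_sites", "k2p"):
            raise ValueError(f"unknown sequence model mode {self.mode!r}")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")


class InfiniteSitesOverflow(RuntimeError):
    """More mutations than available sites; rerun with larger L."""


def mutate_sequences(
    tree: Tree,
    model: SequenceMutationModel,
    L: int,
    seed: int | np.random.Generator | None,
    id_prefix: str = "seq",
) -> SequenceAlignment:
    """Drop Poisson mutations on the genealogy and return leaf sequences."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = as_rng(seed)
    bl = tree.branch_lengths()
    rate = model.mu_per_site * L
    n = tree.n_leaves
    anc = rng.integers(0, 4, size=L)
    seqs = np.tile(anc, (n, 1))
    total = rng.poisson(rate * bl.sum())
    if total > 0:
        branches = rng.choice(tree.n_nodes, size=total, p=bl / bl.sum())
        M = tree.leaf_matrix()
        if model.mode == "infinite_sites":
            if total > L:
                raise InfiniteSitesOverflow(
                    f"{total} mutations for {L} sites; increase L"
                )
            sites = rng.choice(L, size=total, replace=False)
            for b, s in zip(branches, sites):
                derived = (anc[s] + rng.integers(1, 4)) % 4
                seqs[M[b], s] = derived
        else:
            # apply mutations root-down so later events overwrite earlier ones
            order = np.argsort(-tree.time[branches], kind="stable")
            for idx in order:
                b = branches[idx]
                s = rng.integers(0, L)
                carriers = M[b]
                cur = seqs[carriers, s]
                if rng.random() < model.kappa / (model.kappa + 2.0):
                    new = cur ^ 1  # transition partner within purines/pyrimidines
                else:
                    new = (cur + (2 if rng.random() < 0.5 else 3)) % 4
                seqs[carriers, s] = new
    letters = _BASES[seqs]
    ids = [f"{id_prefix}{i:03d}" for i in range(n)]
    return SequenceAlignment(
        sample_ids=ids,
        sequences=[b"".join(row).decode() for row in letters],
    )


# ---------------------------------------------------------------------------
# Microsatellite (two-phase model) mutation
# ---------------------------------------------------------------------------


def tpm_steps(
    count: int, ps: float, delta_g: float, rng: np.random.Generator
) -> np.ndarray:
    """Signed repeat-unit changes under the two-phase model.

    One-step with probability ps; otherwise a multi-step change of
    geometric magnitude with mean delta_g and minimum 2 (sign equiprobable).
    """
    if count == 0:
        return np.zeros(0, dtype=int)
    mag = np.ones(count, dtype=int)
    multi = rng.random(count) >= ps
    n_multi = int(multi.sum())
    if n_multi:
        p = min(1.0, 1.0 / max(delta_g - 1.0, 1e-9))
        mag[multi] = 1 + rng.geometric(p, size=n_multi)
    sign = rng.integers(0, 2, size=count) * 2 - 1
    return mag * sign


def _reflect(sizes: np.ndarray) -> np.ndarray:
    """Reflecting boundary at 2 repeat units."""
    return 2 + np.abs(sizes - 2)


def msat_leaf_sizes(
    tree: Tree,
    mu: float,
    ps: float,
    delta_g: float,
    rng: np.random.Generator,
    root_size: int = 20,
) -> np.ndarray:
    """Allele sizes at the leaves after TPM mutation along the tree.

    The cumulative displacement is reflected at 2 repeats at each node.
    """
    bl = tree.branch_lengths()
    counts = rng.poisson(mu * bl)
    disp = np.zeros(tree.n_nodes, dtype=int)
    nz = np.flatnonzero(counts)
    for b in nz:
        disp[b] = int(tpm_steps(int(counts[b]), ps, delta_g, rng).sum())
    value = np.zeros(tree.n_nodes, dtype=int)
    order = np.argsort(-tree.time, kind="stable")  # root first
    root = order[0]
    value[root] = root_size
    for node in order[1:]:
        value[node] = 2 + abs(value[tree.parent[node]] + disp[node] - 2)
    return value[: tree.n_leaves]


_UNIT_SCENARIO = CoalescentScenario(kind="constant", ne=0.5)


def unit_tree(n: int, rng: np.random.Generator) -> Tree:
    """Genealogy in coalescent units (pair-coalescence rate 1)."""
    return simulate_genealogy(n, _UNIT_SCENARIO, rng)


def msat_locus_equilibrium(
    n_genes: int,
    theta: float,
    ps: float,
    delta_g: float,
    rng: np.random.Generator,
    root_size: int = 20,
) -> np.ndarray:
    """Equilibrium sample of allele sizes at scaled diversity theta = 4*Ne*mu.

    The genealogy is drawn in coalescent units; the per-branch mutation rate
    is then theta/2.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    tree = unit_tree(n_genes, rng)
    return msat_leaf_sizes(tree, theta / 2.0, ps, delta_g, rng, root_size)


def pair_copies_to_genotypes(
    sizes_per_locus: list[np.ndarray],
    locus_names: list[str] | None = None,
    motif_lengths: np.ndarray | None = None,
    id_prefix: str = "ind",
) -> GenotypeMatrix:
    """Pair consecutive gene copies into diploid individuals."""
    n_loci = len(sizes_per_locus)
    n_genes = len(sizes_per_locus[0])
    if n_genes % 2:
        raise ValueError("need an even number of gene copies")
    n = n_genes // 2
    alleles = np.zeros((n, n_loci, 2), dtype=int)
    for j, sizes in enumerate(sizes_per_locus):
        alleles[:, j, 0] = sizes[0::2]
        alleles[:, j, 1] = sizes[1::2]
    names = locus_names or [f"L{j+1:02d}" for j in range(n_loci)]
    motifs = (
        motif_lengths if motif_lengths is not None else np.full(n_loci, 2, dtype=int)
    )
    return GenotypeMatrix(
        sample_ids=[f"{id_prefix}{i:03d}" for i in range(n)],
        locus_names=names,
        motif_lengths=motifs,
        alleles=alleles,
    )


def mutate_microsats(
    trees: list[Tree],
    mu: float,
    ps: float,
    delta_g: float,
    seed: int | np.random.Generator | None,
    root_size: int = 20,
    locus_names: list[str] | None = None,
) -> GenotypeMatrix:
    """TPM mutation over per-locus genealogies (in generations) -> genotypes."""
    rng = as_rng(seed)
    sizes = [
        msat_leaf_sizes(t, mu, ps, delta_g, rng, root_size) for t in trees
    ]
    return pair_copies_to_genotypes(sizes, locus_names=locus_names)


# ---------------------------------------------------------------------------
# Convenience dataset generators (study-scale defaults)
# ---------------------------------------------------------------------------


def simulate_sequences_theta(
    n: int,
    theta: float,
    L: int,
    seed: int | np.random.Generator | None,
    id_prefix: str = "seq",
) -> SequenceAlignment:
    """Constant-size equilibrium alignment at scaled diversity theta.

    Uses a coalescent-unit genealogy with per-gene mutation rate theta/2
    (infinite sites over L positions).
    """
    rng = as_rng(seed)
    tree = unit_tree(n, rng)
    model = SequenceMutationModel(mu_per_site=theta / 2.0 / L)
    return mutate_sequences(tree, model, L, rng, id_prefix=id_prefix)


def simulate_microsat_dataset(
    n_individuals: int,
    n_loci: int,
    theta: float,
    ps: float,
    delta_g: float,
    seed: int | np.random.Generator | None,
) -> GenotypeMatrix:
    """Equilibrium diploid microsatellite dataset at per-locus theta."""
    rng = as_rng(seed)
    sizes = [
        msat_locus_equilibrium(2 * n_individuals, theta, ps, delta_g, rng)
        for _ in range(n_loci)
    ]
    return pair_copies_to_genotypes(sizes)


def simulate_bottleneck_microsats(
    n_individuals: int,
    n_loci: int,
    scenario: CoalescentScenario,
    mu: float,
    ps: float,
    delta_g: float,
    seed: int | np.random.Generator | None,
) -> GenotypeMatrix:
    """Diploid microsatellites under an arbitrary (e.g. bottleneck) scenario."""
    rng = as_rng(seed)
    trees = [
        simulate_genealogy(2 * n_individuals, scenario, rng) for _ in range(n_loci)
    ]
    return mutate_microsats(trees, mu, ps, delta_g, rng)


# ---------------------------------------------------------------------------
# Forward-time simulators (oracles for the Ne estimators)
# ---------------------------------------------------------------------------


def wright_fisher_genotypes(
    ne: int,
    n_loci: int,
    n_generations: int,
    n_alleles: int,
    sample_size: int,
    seed: int | np.random.Generator | None,
) -> GenotypeMatrix:
    """Forward Wright-Fisher population of ``ne`` diploids, unlinked loci.

    Starts from equal allele frequencies, mates at random (two distinct
    parents, one gamete each, free recombination), and samples
    ``sample_size`` individuals without replacement after ``n_generations``.
    Used as the parameter-recovery oracle for the LD-based Ne estimator.
    """
    rng = as_rng(seed)
    pop = rng.integers(1, n_alleles + 1, size=(ne, n_loci, 2))
    for _ in range(n_generations):
        mothers = rng.integers(0, ne, size=ne)
        shift = 1 + rng.integers(0, ne - 1, size=ne)
        fathers = (mothers + shift) % ne  # distinct second parent
        gam_m = np.take_along_axis(
            pop[mothers], rng.integers(0, 2, size=(ne, n_loci, 1)), axis=2
        )[..., 0]
        gam_f = np.take_along_axis(
            pop[fathers], rng.integers(0, 2, size=(ne, n_loci, 1)), axis=2
        )[..., 0]
        pop = np.stack([gam_m, gam_f], axis=2)
    take = rng.choice(ne, size=sample_size, replace=False)
    return GenotypeMatrix(
        sample_ids=[f"wf{i:03d}" for i in range(sample_size)],
        locus_names=[f"L{j+1:02d}" for j in range(n_loci)],
        motif_lengths=np.full(n_loci, 2, dtype=int),
        alleles=pop[take] + 9,  # shift into plausible repeat-unit sizes
    )


def progeny_of_breeders(
    n_breeders: int,
    n_loci: int,
    n_alleles: int,
    n_progeny: int,
    seed: int | np.random.Generator | None,
) -> GenotypeMatrix:
    """Progeny of a tiny breeding pool (oracle for the heterozygote-excess
    number-of-breeders estimator).

    Breeders are split into dams and sires; each offspring draws a random
    dam and sire and one gamete from each.  With few breeders the sexes'
    allele frequencies differ by chance, producing the heterozygote excess
    the estimator inverts.
    """
    if n_breeders < 2:
        raise ValueError("need >= 2 breeders")
    rng = as_rng(seed)
    breeders = rng.integers(1, n_alleles + 1, size=(n_breeders, n_loci, 2))
    n_dams = n_breeders // 2
    dams, sires = breeders[:n_dams], breeders[n_dams:]
    di = rng.integers(0, n_dams, size=n_progeny)
    si = rng.integers(0, len(sires), size=n_progeny)
    gam_d = np.take_along_axis(
        dams[di], rng.integers(0, 2, size=(n_progeny, n_loci, 1)), axis=2
    )[..., 0]
    gam_s = np.take_along_axis(
        sires[si], rng.integers(0, 2, size=(n_progeny, n_loci, 1)), axis=2
    )[..., 0]
    alleles = np.stack([gam_d, gam_s], axis=2) + 9
    return GenotypeMatrix(
        sample_ids=[f"prog{i:03d}" for i in range(n_progeny)],
        locus_names=[f"L{j+1:02d}" for j in range(n_loci)],
        motif_lengths=np.full(n_loci, 2, dtype=int),
        alleles=alleles,
    )


# ---------------------------------------------------------------------------
# ASHW-like fixture (synthetic stand-in built to the published counts)
# ---------------------------------------------------------------------------

STUDY_LOCI = [
    "199/200",
    "417/418",
    "464/465",
    "EV1Pm",
    "EV37Mn",
    "EV94Mn",
    "EV96Mn",
    "GATA028",
    "TAA031",
    "GATA053",
    "GATA417",
]
STUDY_MOTIFS = np.array([2, 2, 2, 2, 2, 2, 2, 4, 3, 4, 4])
#: target distinct-allele counts per locus: EV37Mn carries 12, EV1Pm 3
STUDY_ALLELE_COUNTS = [6, 7, 5, 3, 12, 8, 6, 9, 4, 7, 5]
#: haplotype counts over 47 individuals (decreasing, 7 haplotypes)
STUDY_HAP_COUNTS = [18, 10, 8, 5, 3, 2, 1]


def make_ashw_fixture(
    seed: int = 0, raw: bool = False
) -> tuple[SequenceAlignment, GenotypeMatrix, PopulationPartition]:
    """Deterministic synthetic fixture with the study's structural counts.

    47 individuals; 486-bp mtDNA realising exactly 7 haplotypes over exactly
    24 polymorphic sites; 11 microsatellite loci with allele counts 3-12
    (min at EV1Pm, max at EV37Mn), HWE-consistent genotypes, one missing
    genotype (~0.2% missing).  With ``raw=True`` the genotype matrix gains
    16 planted duplicates and 4 failed (all-missing) samples - 67 in all -
    to exercise the screening path.
    """
    rng = np.random.default_rng(seed)
    L, S, H = 486, 24, 7
    base = rng.integers(0, 4, size=L)
    sites = np.sort(rng.choice(L, size=S, replace=False))
    hap_states = np.tile(base, (H, 1))
    # distribute the 24 variant sites over haplotypes 1..6; haplotype 0 keeps
    # the base state everywhere, so every column is polymorphic and all 7
    # sequences are distinct
    for i, s in enumerate(sites):
        h = 1 + (i % (H - 1))
        hap_states[h, s] = (base[s] + 1 + rng.integers(0, 3)) % 4
    hap_seqs = [b"".join(_BASES[row]).decode() for row in hap_states]

    ids = [f"ASHW{i+1:03d}" for i in range(sum(STUDY_HAP_COUNTS))]
    seqs = []
    for h, c in enumerate(STUDY_HAP_COUNTS):
        seqs.extend([hap_seqs[h]] * c)
    order = rng.permutation(len(ids))
    aln = SequenceAlignment(
        sample_ids=ids, sequences=[seqs[i] for i in order]
    )

    n = len(ids)
    alleles = np.zeros((n, len(STUDY_LOCI), 2), dtype=int)
    for j, k_target in enumerate(STUDY_ALLELE_COUNTS):
        sizes = 8 + np.sort(rng.choice(k_target + 3, size=k_target, replace=False))
        for _ in range(200):
            freqs = rng.dirichlet(np.full(k_target, 2.0))
            draws = rng.choice(sizes, size=(n, 2), p=freqs)
            if len(np.unique(draws)) == k_target:
                alleles[:, j, :] = draws
                break
        else:  # pragma: no cover - extremely unlikely
            raise RuntimeError("failed to realise target allele count")
    alleles[13, 7, :] = MISSING  # one missing genotype: 1/517 = 0.19%

    gm = GenotypeMatrix(
        sample_ids=ids,
        locus_names=list(STUDY_LOCI),
        motif_lengths=STUDY_MOTIFS.copy(),
        alleles=alleles,
    )
    if not raw:
        part = PopulationPartition(assignments={s: "ASHW" for s in ids})
        return aln, gm, part

    dup_of = rng.choice(n, size=16, replace=False)
    dup_ids = [f"ASHWdup{i+1:02d}" for i in range(16)]
    fail_ids = [f"ASHWfail{i+1:02d}" for i in range(4)]
    all_ids = ids + dup_ids + fail_ids
    raw_alleles = np.concatenate(
        [
            alleles,
            alleles[dup_of],
            np.zeros((4, len(STUDY_LOCI), 2), dtype=int),
        ]
    )
    gm_raw = GenotypeMatrix(
        sample_ids=all_ids,
        locus_names=list(STUDY_LOCI),
        motif_lengths=STUDY_MOTIFS.copy(),
        alleles=raw_alleles,
    )
    part = PopulationPartition(assignments={s: "ASHW" for s in all_ids})
    return aln, gm_raw, part
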