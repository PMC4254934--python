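"""Core containers for the inference chain.

Two marker systems are carried side by side: haploid mtDNA control-region
alignments (:class:`SequenceAlignment`, collapsed to a :class:`HaplotypeTable`)
and diploid microsatellite genotypes (:class:`GenotypeMatrix`, allele sizes in
repeat units).  A :class:`PopulationPartition` maps samples to population
labels, and every stochastic test reports through :class:`TestResult` so the
null-distribution provenance (permutation / coalescent / exact) and the seed
are never lost.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: sentinel for a missing microsatellite allele (Genepop "00"/"000")
MISSING = 0

VALID_SEQ_CHARS = frozenset("ACGTN-")


class AlignmentError(ValueError):
    """Sequences violate alignment invariants (unequal lengths, empty)."""


class IdentityError(ValueError):
    """Duplicate or unassigned sample identifiers."""


@dataclass
class SequenceAlignment:
    """Equal-length haploid sequences over {A, C, G, T, -, N}."""

    sample_ids: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("sample_ids and sequences differ in length")
        if not self.sequences:
            raise AlignmentError("empty alignment")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise IdentityError("duplicate sample ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        if next(iter(lengths)) < 1:
            raise AlignmentError("zero-length alignment")
        bad = set("".join(self.sequences)) - VALID_SEQ_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in sequences: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_matrix(self) -> np.ndarray:
        """(n, L) array of single-byte characters."""
        return np.frombuffer("".join(self.sequences).encode(), dtype="S1").reshape(
            self.n, self.length
        )

    def subset(self, ids: Iterable[str]) -> "SequenceAlignment":
        wanted = list(ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in index]
        if missing:
            raise IdentityError(f"unknown sample ids: {missing}")
        return SequenceAlignment(
            sample_ids=wanted,
            sequences=[self.sequences[index[s]] for s in wanted],
        )


@dataclass
class PopulationPartition:
    """Assignment of every sample to exactly one population label."""

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise IdentityError("empty partition")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return list(seen)

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    def labels_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.assignments[s] for s in sample_ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise IdentityError(f"sample not in partition: {exc}") from exc


@dataclass
class HaplotypeTable:
    """Unique sequences with per-population counts.

    ``counts`` has shape (n_haplotypes, n_populations); column sums are the
    population sample sizes.
    """

    haplotype_sequences: list[str]
    counts: np.ndarray
    populations: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.haplotype_sequences), len(self.populations)):
            raise ValueError("counts shape does not match haplotypes x populations")
        if (self.counts < 0).any():
            raise ValueError("negative haplotype counts")
        if (self.counts.sum(axis=1) < 1).any():
            raise ValueError("haplotype with zero total count")
        if len(set(self.haplotype_sequences)) != len(self.haplotype_sequences):
            raise ValueError("haplotype sequences not unique")

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_sequences)

    def population_counts(self, population: str) -> np.ndarray:
        return self.counts[:, self.populations.index(population)]

    def sample_size(self, population: str) -> int:
        return int(self.population_counts(population).sum())


@dataclass
class GenotypeMatrix:
    """Diploid microsatellite genotypes, allele sizes in repeat units.

    ``alleles`` has shape (n_individuals, n_loci, 2) with 0 (:data:`MISSING`)
    marking a missing allele; both alleles of a genotype are missing together.
    ``motif_lengths`` records the repeat-unit size (2/3/4 bp) per locus.
    """

    sample_ids: list[str]
    locus_names: list[str]
    motif_lengths: np.ndarray
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=int)
        self.motif_lengths = np.asarray(self.motif_lengths, dtype=int)
        n, L = len(self.sample_ids), len(self.locus_names)
        if len(set(self.sample_ids)) != n:
            raise IdentityError("duplicate sample ids in genotype matrix")
        if len(set(self.locus_names)) != L:
            raise ValueError("duplicate locus names")
        if self.alleles.shape != (n, L, 2):
            raise ValueError(f"alleles shape {self.alleles.shape} != ({n}, {L}, 2)")
        if self.motif_lengths.shape != (L,):
            raise ValueError("motif_lengths length mismatch")
        if (self.alleles < 0).any():
            raise ValueError("negative allele sizes")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_names)

    def missing_fraction(self) -> float:
        return float((self.alleles[..., 0] == MISSING).mean())

    def locus(self, name: str) -> np.ndarray:
        """(n, 2) allele sizes at one locus (0 = missing)."""
        return self.alleles[:, self.locus_names.index(name), :]

    def genotyped_at(self, locus_index: int) -> np.ndarray:
        """Boolean mask of individuals with data at a locus."""
        return self.alleles[:, locus_index, 0] != MISSING

    def allele_frequencies(self, locus_index: int) -> dict[int, float]:
        """Sample allele frequencies among genotyped individuals."""
        geno = self.alleles[self.genotyped_at(locus_index), locus_index, :]
        if geno.size == 0:
            return {}
        sizes, counts = np.unique(geno, return_counts=True)
        total = counts.sum()
        return {int(s): float(c) / total for s, c in zip(sizes, counts)}

    def subset(self, ids: Iterable[str]) -> "GenotypeMatrix":
        wanted = list(ids)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in wanted]
        return GenotypeMatrix(
            sample_ids=wanted,
            locus_names=list(self.locus_names),
            motif_lengths=self.motif_lengths.copy(),
            alleles=self.alleles[rows].copy(),
        )


@dataclass
class TestResult:
    """A statistic together with its null-distribution provenance."""

    name: str
    statistic: float
    p_value: float | None
    method: str  # 'permutation' | 'coalescent' | 'exact' | 'analytic'
    n_reps: int | None = None
    seed: int | None = None
    flags: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [_clean(x) for x in v]
            return v

        return {
            "name": self.name,
            "statistic": _clean(self.statistic),
            "p_value": _clean(self.p_value),
            "method": self.method,
            "n_reps": self.n_reps,
            "seed": self.seed,
            "flags": list(self.flags),
            "extras": _clean(self.extras),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    """Normalise a seed or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
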