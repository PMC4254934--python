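# coalpop

Population-genetic inference for small, isolated populations, built around
the question a conservation geneticist asks of a remnant whale population:
*is it genetically distinct, has it crashed, and how many animals are
effectively left?*  The package implements the complete chain from raw
marker data to those answers for two marker systems — mtDNA control-region
sequences (haploid, maternally inherited) and diploid microsatellite
genotypes — together with the coalescent simulation engine that supplies
every null distribution.

## What it computes

**Identity screening.** Probability of identity
PI = Π<sub>l</sub> [2(Σp<sub>i</sub>²)² − Σp<sub>i</sub>⁴] and
genotype-identity duplicate removal, so re-sampled individuals never
inflate sample sizes.

**Diversity.** Haplotype diversity Hd = n/(n−1)(1 − Σp<sub>i</sub>²) with
Nei's sampling variance; mean pairwise differences k with Tajima's
variance; per-locus allele counts K, observed and unbiased expected
heterozygosity (H<sub>o</sub>, H<sub>e</sub>); exact/Monte-Carlo HWE
probability tests and genotypic LD permutation tests (log-likelihood G).

**Differentiation.** Two-level AMOVA F<sub>ST</sub> (haplotype identity
distance) and Φ<sub>ST</sub> (pairwise-difference or K2P distance);
Weir–Cockerham θ for microsatellites; significance by permuting
individuals across populations (default 10,000 permutations, p-values
with the +1 correction, never 0).

**Bottleneck detection.** Garza–Williamson M = k/(r+1) with critical
values Mc(θ) from equilibrium coalescent simulation under a two-phase
mutation model (one-step probability p<sub>s</sub>, mean multistep size
Δ<sub>g</sub>), scanned over historical diversity θ = 4N<sub>e</sub>μ;
the Cornuet–Luikart heterozygosity-excess Wilcoxon test against
equilibrium H<sub>eq</sub> conditioned on the observed allele count; and
the allele-frequency mode-shift (L-shape) check.

**Demographic stability from sequences.** Tajima's D, Ramos-Onsins &
Rozas' R2 and Harpending's raggedness rg, each with p-values from
fixed-S neutral coalescent simulation (upper tail = decline-oriented).

**Contemporary effective size.** The LD method (Burrows composite r²,
sampling expectation removed, inverted through
E[r²<sub>drift</sub>] = 1/(3N<sub>e</sub>) + 0.69/N<sub>e</sub>²) across
minor-allele-frequency thresholds {0.05, 0.02, 0.01}, and the
heterozygote-excess number of breeders
N<sub>b</sub> = 1/(2D̄) + 1/(2(D̄+1)).

**Divergence-time conversion.** Scaled isolation-with-migration outputs
(θ = 4N<sub>e</sub>μ, T = t/2N<sub>e</sub>, M = 2N<sub>e</sub>m) to
calendar years, female N<sub>e</sub> and migrants per generation, given a
per-site substitution rate, sequence length and generation time.

## Worked example

The repository carries a deterministic synthetic dataset shaped like a
small isolated whale population: 67 raw genotype records (16 planted
re-samples, 4 failed extractions) over 11 microsatellite loci, and a
486-bp mtDNA alignment for the 47 unique individuals realising 7
haplotypes over 24 polymorphic sites.  The analysis chain is a sequence
of numbered drivers:

```bash
python analysis/01_simulate_dataset.py
python analysis/02_screen_duplicates.py
python analysis/03_diversity.py
```

which print

```
67 raw records -> 47 unique individuals
removed: 20 (16 duplicate pairs)
overall PI = 2.27e-12; threshold for confident exclusion 1/1081 = 0.000925 -> confident
mtDNA: n=47, 7 haplotypes, S=24
  Hd = 0.7780 +- 0.0380; k = 4.2923 +- 2.4023
microsatellites: mean K = 6.55, Ho = 0.773, He = 0.764
HWE across loci (Fisher): p = 0.889
LD: 1/55 locus pairs nominally significant at 0.05
```

PI far below 1/#pairs means two records matching at all loci are the same
animal, not a coincidence — the 16 removals are safe.  The genotypes are
HWE-consistent and effectively unlinked, so the downstream estimators'
assumptions hold.  Continuing,

```bash
python analysis/05_bottleneck.py
python analysis/06_neutrality.py
python analysis/07_effective_size.py
python analysis/08_divergence_time.py
```

```
observed mean M = 0.7446 over 11 loci
conservative TPM (ps=0.9, dg=3.5): theta* = 2.0, pre-bottleneck Ne = 1000; het-excess Wilcoxon p = 0.0005
...
LD Ne (pcrit=0.05): 502.6 [114.5, inf]
heterozygote-excess Nb: 36.0 [12.0, inf] (D-bar = 0.0141)
mu per gene per generation = 0.0005333
stockC_T0.1684: t = 58,696 y (2,730 generations), female Ne = 8,106, 2.835 migrants/generation
T0.2: t = 69,711 y (3,242 generations), female Ne = 8,106, 2.835 migrants/generation
```

Read the bottleneck block as: the observed mean M-ratio falls below the
simulated equilibrium critical value Mc for every historical diversity
θ ≤ θ\*; a real population with pre-crash N<sub>e</sub> up to
θ\*/(4μ) would therefore show this signature only after a size
reduction.  The divergence block converts a scaled split time into
calendar years: with θ = 17.291 and the control-region constants
(5.2%/Myr over 477 bp, 21.5-year generations), T = 0.1684 means a split
≈ 58,700 years ago, and T = 0.2 ≈ 70,000 years ago.
`analysis/04_differentiation.py` adds Φ<sub>ST</sub>/F<sub>ST</sub>
against a simulated comparison population.

The same chain runs from a shell on any FASTA + Genepop pair via the
`coalpop` CLI (`coalpop all --config config.yaml --seed 1`); subcommands
`simulate`, `screen`, `diversity`, `bottleneck`, `neutrality`, `ne` and
`divergence` expose the stages individually.

Real deposited haplotypes for the motivating population can be fetched
with `scripts/fetch_genbank_haplotypes.py` (network required); the
synthetic fixture stands in for them everywhere else.

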