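# Methods

This note records the models, estimators, numerical conventions and
design choices behind `coalpop`, and what the simulation studies do and
do not establish.

## Data model and missing-data policy

Sequences are equal-length alignments over {A,C,G,T,-,N}; microsatellite
genotypes are unordered pairs of allele sizes in **repeat units** (motif
lengths travel in a YAML sidecar because Genepop cannot encode them;
half-missing genotypes are treated as fully missing).  For all
pairwise-difference statistics we use complete deletion: columns
containing `-` or `N` are removed before distances are computed, and a
column counts as segregating only if two or more distinct non-missing
states remain.  Terminal alignment columns containing any gap can be
trimmed with `truncate_gapped_ends` (interior gaps untouched), the
convention required by samplers that cannot handle gaps.  Coordinates
are 0-based internally, 1-based in human-readable reports.

## Identity screening

Duplicate detection defaults to zero tolerated mismatching loci, with
near-matches at one locus reported for operator review; the probability
of identity PI (per locus 2(Σp²)² − Σp⁴, multiplied across loci) is
logged against 1/(number of pairwise comparisons) as the criterion for
confident exclusion.  The mismatch tolerance is our choice; it is
exposed as a parameter.

## Diversity and locus-quality tests

He uses the 2n-copy unbiased correction (2n/(2n−1))(1 − Σp²) so tests
have exact expectations at small n.  The HWE probability test is the
conditional exact test: for diallelic loci we enumerate all heterozygote
counts compatible with the allele counts (Levene's distribution); for
three or more alleles we use a Monte-Carlo randomisation of the flat
allele array (10,000 shuffles by default, seeded), with ties counted as
extreme and the +1 estimator so p is never 0.  Full enumeration of
multi-allelic genotype arrays was deliberately not implemented — the
diallelic path covers the exact-enumeration need and the chain handles
the rest.  The LD test permutes one locus's genotypes across individuals
and uses the log-likelihood G statistic on the two-locus genotype table
(only Σ O log O varies under fixed margins, which is what is computed);
pairs with fewer than five jointly genotyped individuals or a
monomorphic member are flagged not-testable.  The across-loci HWE
combination is Fisher's method — the combination rule is a package
choice and is labelled as such in outputs.

## Differentiation

Sequence statistics are two-level AMOVA ratios σ²a/(σ²a+σ²w) computed
from squared inter-individual distances: haplotype identity (0/1) for
FST, pairwise differences (default) or K2P for ΦST.  K2P distances are
undefined (infinite) for saturated pairs; they propagate as such rather
than being silently clamped.  Microsatellite FST is Weir & Cockerham's θ
with variance components summed over alleles and loci; negative
components are retained in the sums and the final ratio floored at −1.
Permutation tests shuffle individuals between the two populations with
sizes fixed; p = (1 + #{perm ≥ obs})/(n_perm + 1).  Raw p-values are
reported without multiple-testing correction (a Bonferroni column is
emitted for reference only).  A vectorised permutation path
(`phist_permutation_test`) makes the 10,000-permutation default cheap
and is verified against the generic implementation in the tests.

## Coalescent engine

Genealogies follow the Kingman coalescent with pairwise rate 1/(2Ne(t))
per generation and piecewise-constant Ne; diploid loci are simulated
with 2× gene copies and consecutive copies paired into individuals
(equivalent to random union of gametes under exchangeability).  The
two-population scenario is a structured coalescent with symmetric
backward migration rate m per lineage per generation, merging into an
ancestral population of size `ne_a` at the split time.  Sequence
mutation is infinite-sites by default (each mutation a fresh site; an
explicit error suggests a larger L on overflow) or finite-sites K2P with
transition probability κ/(κ+2).  Microsatellite mutation is the
two-phase model: ±1 repeat with probability p_s, otherwise a multistep
change of geometric magnitude with mean Δ_g and minimum 2 (sign
equiprobable) — the geometric tail law is stated explicitly because the
reference descriptions leave it implicit.  Allele sizes reflect at 2
repeats; the reflection is applied to the cumulative displacement at
each tree node rather than per mutation event, a simplification that is
inactive in practice because the root size is 20 repeats.  All
entry points take explicit seeds; fixed seed ⇒ identical output.

## Synthetic study-scale fixture

The fixture emulates the structure of a small isolated population
sample: 47 individuals; a 486-bp alignment realising exactly 7
haplotypes over exactly 24 polymorphic sites (variant sites distributed
over six non-reference haplotypes; haplotype counts 18/10/8/5/3/2/1); 11
microsatellite loci with allele counts spanning 3–12 (minimum at EV1Pm,
maximum at EV37Mn, the panel's locus names), genotypes drawn in HWE from
Dirichlet(2) frequencies re-drawn until the target allele count is
realised; one missing genotype (0.19%).  The raw variant plants 16 exact
duplicates and 4 failed samples (67 records) to exercise screening.
Realism is structural — counts, ranges, missingness — not an attempt to
reproduce any real genotypes (which are not public); sequences have a
star-like haplotype topology, so fixture-based checks validate
book-keeping and screening, not demographic inference on real data.

## Bottleneck tests

Mc(θ) is the empirical 5th percentile of the replicate **mean** M across
loci (matching the "critical value below which" convention), simulated
at each θ on a shared grid (default 0.004–5).  Within a replicate the
same genealogies serve all grid points and mutations are coupled across
θ by Poisson thinning of the θ_max stream, so the curve is smooth in θ
at moderate replicate counts; monomorphic simulated loci score M = 1,
while monomorphic *observed* loci are excluded (they carry no range
information for the data at hand).  θ\* is the largest grid θ whose Mc
exceeds the observed mean M, converted to a pre-bottleneck size
Ne = θ\*/(4μ) with μ = 5×10⁻⁴ by default.

The heterozygosity-excess test conditions the equilibrium null on the
observed allele count k per locus: θ is tuned by bisection (16
iterations on log θ, 48 simulations per evaluation) until E[#alleles]
matches k, then rejection sampling keeps exactly-k simulations (capped
at 10⁵ attempts).  Per locus the observed He is located in the null via
the probability-integral transform u = P(Heq < He); the one-tailed
Wilcoxon signed-rank across loci tests whether the u's exceed ½.  We
rank u − ½ rather than the classical standardised difference
(He − mean Heq)/sd because the Heq distribution is skewed, which makes
the standardised differences asymmetric under the null and inflated the
measured type-I error to 0.05–0.08; the transform is symmetric by
construction and restores the nominal size (the achievable size of the
11-locus Wilcoxon at α = 0.05 is 0.0415).  The classical DH/sd values
are still reported per locus.  Conditional nulls are cached by
(n, k, p_s, Δ_g, reps) so calibration studies reuse them.

The mode-shift check pools allele frequencies across polymorphic loci
into ten right-closed classes (0–0.1], …, (0.9–1.0]; L-shaped iff the
lowest class is the strict mode.

## Neutrality statistics

D uses the standard constants (a1, a2, b1, b2, c1, c2, e1, e2); R2 uses
U_i = number of sites whose minor state occurs exactly once and is
carried by sequence i (for n = 2 both sequences carry a singleton — the
tie convention is fixed by the oracle tests); the mismatch distribution
runs from 0 to the maximum observed difference with no padding beyond it
(this affects rg on concentrated distributions; implementations differ,
so the choice is stated).  Significance is by fixed-S conditioning: S
mutations placed multinomially by branch length on constant-size
coalescent genealogies (a θ-conditioned mode is not the default because
the fixed-S convention matches the standard sequence packages).  Tail
orientation is explicit; `upper` is the decline-oriented convention for
D and R2.

## Effective-size estimators

**LD method.**  For each locus pair the Burrows composite Δ per allele
pair (with the n/(n−1) correction) is squared and pooled over allele
pairs as a ratio of sums with weights p(1−p)q(1−q); locus pairs are
weighted by (#allele comparisons × joint sample size).  Pooling rather
than averaging per-pair ratios matters: the mean-of-ratios form dilutes
the drift signal by ~30% at multi-allelic loci (verified against the
1/(3Ne) expectation with diallelic vs 8-allele forward simulations).
The no-drift expectation is estimated for the data at hand by shuffling
individuals at one locus of each pair (20 shuffles, seeded), which
reproduces this estimator's finite-sample expectation exactly; the
Waples (2006) analytic corrections (1/S + 3.19/S², S ≥ 30; 0.0018 +
0.907/S + 4.44/S² otherwise) are reported alongside and used when
permutation is disabled — at S = 47 the analytic value is ~4% high for
the pooled estimator, enough to bias Ne upward by ~40%.  The corrected
signal r′ is inverted through the random-mating drift relation
r′ = 1/(3Ne) + 0.69/Ne² (positive quadratic root; r′ ≤ 0 ⇒ +∞).
Random mating, not monogamy, is assumed.  CIs are delete-one jackknife
over locus pairs on r′, pushed through the inversion.

**Heterozygote excess.**  Per allele D = (h_obs − h_exp)/h_exp with the
Levene-corrected h_exp = 2p(1−p)·2n/(2n−1); D̄ is the unweighted mean
over alleles of polymorphic loci; N̂b = 1/(2D̄) + 1/(2(D̄+1)) (the
Pudovkin-family inversion), D̄ ≤ 0 ⇒ +∞; a t-interval on the per-allele
D values gives the CI.  The estimator targets the number of breeders
that produced the sampled cohort, which is why the forward oracle
simulates dam/sire pools.

## Divergence-time conversion

μ_gene/generation = μ_site/year × L × G; Ne = θ/(4μ);
t_generations = Tθ/(2μ); t_years = t_generations × G; migrants per
generation = M/2.  The per-Myr rate is read **per site** — with the
477-bp length and 21.5-year generations this reproduces ≈70 kyr at
T = 0.2 while the alternative per-gene reading does not.  With the
tabulated T = 0.1684 the formula gives ≈58.7 kyr; both values are
reported because the published ~70 kyr figure averages over sampler runs
whose exact T is not recoverable.  Ne is labelled *female* effective
size for mtDNA.

## Validation studies (what passing shows)

All studies run at study-scale conditions: n = 47 diploids, 11 TPM loci
(θ = 1 per locus for calibration), 486-bp sequences at θ = 5.

* *Type-I calibration* (500 datasets per test, α = 0.05): HWE, LD,
  heterozygosity excess, D, R2 and permutation-ΦST reject within the
  99% binomial band of 0.05.  Null replicate counts: 1000 for MC/
  permutation tests, 1000 for conditional Heq nulls, 1000 fixed-S
  simulations per observed S (cached).
* *Bottleneck suite*: Ne 5000 → 50 three generations ago versus matched
  equilibrium (θ = 10): mean M strictly lower (150 paired datasets),
  heterozygosity-excess power ≈ 0.19–0.22 ≥ 3α (300 datasets), and
  Mc(θ) non-increasing for both TPM parameter sets (300 coupled
  replicates).  The M depression is modest at 3 generations — the
  genealogy retains ~25 effective founder lineages — so the contrast is
  asserted on means, not per dataset.
* *Oracle equivalence*: D, R2, k, Hd, rg, ΦST and Weir–Cockerham θ match
  independent loop-based reimplementations to 10⁻¹⁰ relative tolerance
  on 100 simulated datasets; the coalescent engine's E[S] matches both
  the Watterson closed form and msprime at matched parameters.
* *Parameter recovery*: LD-Ne median within 25% of truth (Ne = 100,
  n = 47, 11 loci, 10 forward generations, 200 replicates; jackknife CI
  coverage ≥ 80%); heterozygote-excess Nb recovers the ordering of
  {2, 10, 50} true breeders.

These establish internal consistency and statistical calibration under
the stated models.  They do not establish robustness to real-data
pathologies the generator omits: genotyping error and allelic dropout,
null alleles, inbreeding, overlapping generations, population structure
within samples, or selection on linked sites.

## Replicate-count and runtime choices

Defaults mirror analysis practice (10,000 permutations/simulations); the
validation studies use 300–1000 replicates per null and 120–500 datasets
per rate, chosen so the whole battery runs in minutes on a single core
while keeping Monte-Carlo error well inside the asserted tolerances.
Seeds derive from a single master seed via `numpy` SeedSequence; every
reported statistic carries its seed and replicate count.
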