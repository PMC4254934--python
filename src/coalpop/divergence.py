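"""Conversion of scaled isolation-with-migration parameters to natural units.

An isolation-with-migration sampler reports, per gene:
theta = 4*Ne*mu (mu per gene per generation), T = t/(2*Ne) generations
scaled by effective size, and M = 2*Ne*m migrant gene copies per
generation.  Given a per-site per-year substitution rate, the sequence
length and the generation time, these convert to calendar years, a
(female, for mtDNA) effective size and migrants per generation:

    mu_gene_gen = mu_site_year * L * G
    Ne = theta / (4 mu_gene_gen)
    t_gen = T * 2 * Ne = T * theta / (2 mu_gene_gen)
    t_years = t_gen * G
    migrants/generation = M / 2
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class ScaledDivergenceParams:
    """theta = 4 Ne mu (per gene per generation); T = t/(2 Ne); M = 2 Ne m."""

    theta: float
    T: float
    M: float = 0.0

    def __post_init__(self) -> None:
        if self.theta < 0 or self.T < 0 or self.M < 0:
            raise ValueError("scaled parameters must be >= 0")


@dataclass
class ConversionConstants:
    """Defaults for the humpback mtDNA control region.

    mu_site_year: substitutions/site/year (5.2e-8 = 5.2% per Myr, read per
    site); L: analysed sites (477 bp after end-truncation); G: generation
    time in years (21.5).
    """

    mu_site_year: float = 5.2e-8
    L: int = 477
    G: float = 21.5

    def __post_init__(self) -> None:
        if self.mu_site_year <= 0 or self.L <= 0 or self.G <= 0:
            raise ValueError("conversion constants must be > 0")

    @property
    def mu_gene_per_generation(self) -> float:
        return self.mu_site_year * self.L * self.G


@dataclass
class DivergenceEstimate:
    t_years: float
    t_generations: float
    ne_female: float
    migrants_per_generation: float


def scale_divergence(
    p: ScaledDivergenceParams, c: ConversionConstants = ConversionConstants()
) -> DivergenceEstimate:
    """Convert (theta, T, M) to years, female effective size and migrants.

    ``ne_female`` is labelled female because the gene is maternally
    inherited mtDNA; for autosomal data read it as plain Ne.
    """
    mu = c.mu_gene_per_generation
    if mu <= 0:
        raise ValueError("zero mutation rate")
    ne = p.theta / (4.0 * mu)
    t_gen = p.T * p.theta / (2.0 * mu)
    return DivergenceEstimate(
        t_years=t_gen * c.G,
        t_generations=t_gen,
        ne_female=ne,
        migrants_per_generation=p.M / 2.0,
    )


def scaled_params_from_truth(
    t_generations: float, ne: float, m: float, mu_gene_per_generation: float
) -> ScaledDivergenceParams:
    """Inverse mapping (for round-trip checks against simulation truth)."""
    return ScaledDivergenceParams(
        theta=4.0 * ne * mu_gene_per_generation,
        T=t_generations / (2.0 * ne),
        M=2.0 * ne * m,
    )
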