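"""Pipeline orchestration: the full analysis chain on one dataset.

Stage order mirrors the inference chain: duplicate screening, diversity,
pairwise differentiation, the bottleneck suite, sequence neutrality tests,
contemporary Ne, and the divergence-time conversion.  Each stage consumes
in-memory objects but writes its own JSON/TSV with seed and replicate
provenance, so any stage can be audited or re-run in isolation.  Stage
failures are recorded and the pipeline continues.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bottleneck as bn
from . import differentiation as diff
from . import diversity as dv
from . import identity, neutrality
from . import ne as ne_mod
from .alignment import (
    collapse_haplotypes,
    hamming_distance_matrix,
    segregating_sites,
    truncate_gapped_ends,
)
from .datatypes import (
    GenotypeMatrix,
    PopulationPartition,
    SequenceAlignment,
    spawn_seeds,
)
from .divergence import ConversionConstants, ScaledDivergenceParams, scale_divergence
from .io import read_fasta_alignment, read_genepop, read_partition_yaml


@dataclass
class PipelineConfig:
    """Inputs and tuning for a full run.

    Replicate counts default to the analysis-scale values (10,000
    permutations / simulations); ``fast=True`` drops them to 1,000 for
    smoke runs.  ``seed`` is mandatory: every stage derives its own child
    seed from it.
    """

    fasta: str | None = None
    genepop: str | None = None
    locus_config: str | None = None
    partition: str | None = None
    focal_population: str = "pop1"
    comparison_populations: list[str] = field(default_factory=list)
    n_permutations: int = 10_000
    n_simulations: int = 10_000
    het_excess_reps: int = 1000
    mc_reps: int = 1000
    theta_grid: tuple = bn.DEFAULT_THETA_GRID
    tpm_sets: dict = field(
        default_factory=lambda: {
            "conservative": bn.CONSERVATIVE_TPM,
            "realistic": bn.REALISTIC_TPM,
        }
    )
    pcrits: tuple = (0.05, 0.02, 0.01)
    mu_msat: float = 5e-4
    conversion: ConversionConstants = field(default_factory=ConversionConstants)
    scaled_params: ScaledDivergenceParams | None = None
    seed: int = 0
    fast: bool = False

    def __post_init__(self) -> None:
        if self.fast:
            self.n_permutations = 1000
            self.n_simulations = 1000
            self.het_excess_reps = 500
            self.mc_reps = 500
        if min(self.n_permutations, self.n_simulations) < 100:
            raise ValueError("replicate counts must be >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        conv = raw.pop("conversion", None)
        sp = raw.pop("scaled_params", None)
        cfg = cls(**raw)
        if conv:
            cfg.conversion = ConversionConstants(**conv)
        if sp:
            cfg.scaled_params = ScaledDivergenceParams(**sp)
        return cfg


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))


def _input_hash(*objs) -> str:
    h = hashlib.sha256()
    for o in objs:
        h.update(repr(o).encode())
    return h.hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    aln: SequenceAlignment | None = None,
    gm: GenotypeMatrix | None = None,
    part: PopulationPartition | None = None,
) -> dict:
    """Execute all stages; returns the consolidated report dictionary.

    Inputs may be passed in memory or loaded from the config paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if aln is None and config.fasta:
        aln = read_fasta_alignment(config.fasta)
    if gm is None and config.genepop:
        gm, gen_part = read_genepop(config.genepop, config.locus_config)
        part = part or gen_part
    if part is None and config.partition:
        part = read_partition_yaml(config.partition)
    if gm is None and aln is None:
        raise ValueError("no inputs: provide an alignment and/or genotypes")
    if part is None:
        ids = gm.sample_ids if gm is not None else aln.sample_ids
        part = PopulationPartition({s: config.focal_population for s in ids})

    focal = config.focal_population
    if focal not in part.populations:
        focal = part.populations[0]

    seeds = spawn_seeds(config.seed, 8)
    report: dict = {
        "seed": config.seed,
        "input_hash": _input_hash(
            aln.sequences if aln else None, gm.alleles.tolist() if gm is not None else None
        ),
        "stages": {},
        "errors": {},
    }

    def _stage(name, fn):
        try:
            result = fn()
            report["stages"][name] = result
            _write_json(result, out / f"{name}.json")
        except Exception as exc:  # nonfatal: record and continue
            report["errors"][name] = f"{type(exc).__name__}: {exc}"

    # --- screening -------------------------------------------------------
    def screen():
        nonlocal gm, part
        if gm is None:
            return {"skipped": "no genotypes"}
        screened, removed, pairs = identity.screen_duplicates(gm)
        _, pi = identity.probability_of_identity(screened)
        res = {
            "n_input": gm.n,
            "n_retained": screened.n,
            "removed": removed,
            "n_duplicate_pairs": len(pairs),
            "overall_PI": pi,
        }
        gm = screened
        part = PopulationPartition(
            {s: p for s, p in part.assignments.items() if s in set(gm.sample_ids)}
        )
        return res

    _stage("screen", screen)

    # --- diversity -------------------------------------------------------
    def diversity():
        res: dict = {}
        if aln is not None:
            focal_ids = [s for s in part.samples(focal) if s in aln.sample_ids]
            sub = aln.subset(focal_ids) if focal_ids else aln
            ht = collapse_haplotypes(sub, part)
            hd, hd_sd = dv.haplotype_diversity(ht, focal)
            k, k_sd = dv.mean_pairwise_differences(sub)
            S, _ = segregating_sites(sub)
            res["sequence"] = {
                "n": sub.n,
                "n_haplotypes": ht.n_haplotypes,
                "S": S,
                "Hd": hd,
                "Hd_sd": hd_sd,
                "k": k,
                "k_sd": k_sd,
            }
        if gm is not None:
            ids = [s for s in part.samples(focal) if s in gm.sample_ids]
            summ = dv.locus_summaries(gm, ids or None)
            summ.to_csv(out / "diversity_loci.tsv", sep="\t")
            hwe = {}
            for locus in gm.locus_names:
                tr = dv.hwe_probability_test(
                    gm, locus, ids or None, reps=config.n_simulations, seed=seeds[1]
                )
                hwe[locus] = tr.to_dict()
            valid = [v["p_value"] for v in hwe.values() if v["p_value"] is not None]
            res["microsat"] = {
                "per_locus": summ.to_dict(orient="index"),
                "K_mean": float(summ["K"].mean()),
                "Ho_mean": float(summ["Ho"].mean()),
                "He_mean": float(summ["He"].mean()),
                "hwe": hwe,
                "hwe_across_loci_fisher": dv.combine_across_loci(valid)
                if valid
                else None,
            }
        return res

    _stage("diversity", diversity)

    # --- differentiation -------------------------------------------------
    def differentiation():
        res = {}
        pops = [p for p in (config.comparison_populations or part.populations)
                if p != focal]
        if aln is not None and pops:
            ht = collapse_haplotypes(aln, part)
            shared, private = diff.shared_haplotype_matrix(ht)
            res["shared_haplotypes"] = {
                "populations": ht.populations,
                "matrix": shared.tolist(),
                "private": private,
            }
            rows = {}
            for pop in pops:
                ids = part.samples(focal) + part.samples(pop)
                sub = aln.subset([s for s in ids if s in aln.sample_ids])
                d2 = hamming_distance_matrix(sub)
                labels = np.array(
                    [part.assignments[s] for s in sub.sample_ids]
                )
                tr = diff.phist_permutation_test(
                    d2, labels, n_perm=config.n_permutations, seed=seeds[2]
                )
                fst_h = diff.pairwise_fst_haplotype(ht, focal, pop)
                rows[pop] = {
                    "PhiST": tr.statistic,
                    "PhiST_p": tr.p_value,
                    "FST_haplotype": fst_h,
                    "bonferroni_alpha": 0.05 / max(len(pops), 1),
                }
            res["mtDNA"] = rows
        if gm is not None and pops:
            rows = {}
            for pop in pops:
                try:
                    fst = diff.pairwise_fst_microsat(gm, part, focal, pop)
                except ValueError:
                    continue
                rows[pop] = {"FST_microsat": fst}
            if rows:
                res["microsat"] = rows
        return res or {"skipped": "single population"}

    _stage("differentiation", differentiation)

    # --- bottleneck ------------------------------------------------------
    def bottleneck():
        if gm is None:
            return {"skipped": "no genotypes"}
        ids = [s for s in part.samples(focal) if s in gm.sample_ids] or None
        mres = bn.m_ratio(gm, ids)
        res = {
            "M_per_locus": mres.per_locus,
            "M_mean": mres.mean,
            "models": {},
        }
        n_genes = 2 * (len(ids) if ids else gm.n)
        for label, tpm_kw in config.tpm_sets.items():
            tpm = bn.TwoPhaseModel(**tpm_kw)
            mc = bn.simulate_mc(
                n_genes,
                gm.n_loci,
                tpm,
                theta_grid=config.theta_grid,
                reps=config.mc_reps,
                seed=seeds[3],
            )
            verdict = bn.m_ratio_verdict(mc, mres.mean, mu=config.mu_msat)
            het = bn.het_excess_test(
                gm, tpm, ids, reps=config.het_excess_reps, seed=seeds[4]
            )
            res["models"][label] = {
                "tpm": tpm_kw,
                "verdict": verdict,
                "het_excess": het.to_dict(),
            }
            pd.DataFrame(
                {"theta": mc.theta_grid, "Mc": mc.mc}
            ).to_csv(out / f"mc_curve_{label}.tsv", sep="\t", index=False)
        counts, l_shaped = bn.mode_shift_test(gm, ids)
        res["mode_shift"] = {
            "class_counts": counts.tolist(),
            "L_shaped": l_shaped,
        }
        return res

    _stage("bottleneck", bottleneck)

    # --- neutrality ------------------------------------------------------
    def neut():
        if aln is None:
            return {"skipped": "no sequences"}
        ids = [s for s in part.samples(focal) if s in aln.sample_ids]
        sub = aln.subset(ids) if ids else aln
        sub = truncate_gapped_ends(sub)
        res = {}
        d = neutrality.tajimas_d(sub)
        r2 = neutrality.r2_statistic(sub)
        mismatch, rg = neutrality.mismatch_raggedness(sub)
        S = d.extras.get("S", 0)
        cache: dict = {}
        for name, tr, tail in (
            ("tajimas_D", d, "upper"),
            ("R2", r2, "upper"),
            ("raggedness", None, "upper"),
        ):
            obs = rg if name == "raggedness" else tr.statistic
            if S and not np.isnan(obs):
                pv = neutrality.coalescent_pvalue(
                    "rg" if name == "raggedness" else ("D" if name == "tajimas_D" else "R2"),
                    obs,
                    sub.n,
                    S,
                    reps=config.n_simulations,
                    seed=seeds[5],
                    tail=tail,
                    null_cache=cache,
                )
                res[name] = pv.to_dict()
            else:
                res[name] = {"statistic": None, "flags": ["undefined: S=0"]}
        pd.DataFrame(
            {"differences": np.arange(len(mismatch)), "frequency": mismatch}
        ).to_csv(out / "mismatch.tsv", sep="\t", index=False)
        res["mismatch_classes"] = mismatch.tolist()
        return res

    _stage("neutrality", neut)

    # --- effective size --------------------------------------------------
    def ne_stage():
        if gm is None:
            return {"skipped": "no genotypes"}
        ids = [s for s in part.samples(focal) if s in gm.sample_ids] or None
        res = {"LD": {}, "het_excess": None}
        for p in config.pcrits:
            est = ne_mod.ld_ne(gm, ids, pcrit=p, seed=seeds[6])
            res["LD"][str(p)] = {
                "Ne": est.estimate,
                "ci": [est.ci_low, est.ci_high],
                "n_locus_pairs": est.n_units,
            }
        hb = ne_mod.het_excess_nb(gm, ids)
        res["het_excess"] = {
            "Nb": hb.estimate,
            "ci": [hb.ci_low, hb.ci_high],
            "D_mean": hb.details["D_mean"],
        }
        return res

    _stage("ne", ne_stage)

    # --- divergence conversion -------------------------------------------
    def divergence():
        if config.scaled_params is None:
            return {"skipped": "no scaled parameters supplied"}
        est = scale_divergence(config.scaled_params, config.conversion)
        return {
            "t_years": est.t_years,
            "t_generations": est.t_generations,
            "Ne_female": est.ne_female,
            "migrants_per_generation": est.migrants_per_generation,
        }

    _stage("divergence", divergence)

    _write_json(report, out / "report.json")
    (out / "report.md").write_text(make_report(report))
    return report


def make_report(report: dict) -> str:
    """Human-readable Markdown summary of the stage outputs."""
    lines = ["# Population-genetic analysis report", ""]
    lines.append(f"Master seed: {report.get('seed')}  ")
    lines.append(f"Input hash: {report.get('input_hash')}")
    stages = report.get("stages", {})

    def fmt(x):
        if isinstance(x, float):
            return f"{x:.4g}"
        return str(x)

    if "screen" in stages and "n_retained" in stages["screen"]:
        s = stages["screen"]
        lines += [
            "",
            "## Sample screening",
            f"- {s['n_input']} samples in, {s['n_retained']} retained "
            f"({len(s['removed'])} removed; overall PI = {fmt(s['overall_PI'])})",
        ]
    if "diversity" in stages:
        d = stages["diversity"]
        lines += ["", "## Diversity"]
        if "sequence" in d:
            q = d["sequence"]
            lines.append(
                f"- mtDNA: n={q['n']}, {q['n_haplotypes']} haplotypes, "
                f"S={q['S']}, Hd={fmt(q['Hd'])} ± {fmt(q['Hd_sd'])}, "
                f"k={fmt(q['k'])} ± {fmt(q['k_sd'])}"
            )
        if "microsat" in d:
            q = d["microsat"]
            lines.append(
                f"- microsatellites: mean K={fmt(q['K_mean'])}, "
                f"Ho={fmt(q['Ho_mean'])}, He={fmt(q['He_mean'])}; "
                f"HWE across loci (Fisher) p={fmt(q['hwe_across_loci_fisher'])}"
            )
    if "differentiation" in stages and "mtDNA" in stages.get("differentiation", {}):
        lines += ["", "## Pairwise differentiation (raw p-values)"]
        for pop, row in stages["differentiation"]["mtDNA"].items():
            lines.append(
                f"- vs {pop}: PhiST={fmt(row['PhiST'])} (p={fmt(row['PhiST_p'])}), "
                f"haplotype FST={fmt(row['FST_haplotype'])}"
            )
    if "bottleneck" in stages and "M_mean" in stages.get("bottleneck", {}):
        b = stages["bottleneck"]
        lines += ["", "## Bottleneck tests", f"- observed mean M = {fmt(b['M_mean'])}"]
        for label, mod in b["models"].items():
            v = mod["verdict"]
            het_p = mod["het_excess"]["p_value"]
            lines.append(
                f"- {label} TPM: theta* = {v['theta_star']}, pre-bottleneck "
                f"Ne ≈ {fmt(v['ne_pre_bottleneck']) if v['ne_pre_bottleneck'] else 'n/a'}; "
                f"het-excess Wilcoxon p = {fmt(het_p)}"
            )
        ms = b["mode_shift"]
        lines.append(
            f"- allele frequency classes {ms['class_counts']} -> "
            f"{'L-shaped (no mode shift)' if ms['L_shaped'] else 'mode-shifted'}"
        )
    if "neutrality" in stages and "tajimas_D" in stages.get("neutrality", {}):
        nn = stages["neutrality"]
        lines += ["", "## Neutrality / demographic stability"]
        for key in ("tajimas_D", "R2", "raggedness"):
            row = nn.get(key, {})
            if row.get("statistic") is not None:
                lines.append(
                    f"- {key} = {fmt(row['statistic'])} "
                    f"(upper-tail coalescent p = {fmt(row['p_value'])})"
                )
    if "ne" in stages and "LD" in stages.get("ne", {}):
        q = stages["ne"]
        lines += ["", "## Contemporary effective size"]
        for pcrit, row in q["LD"].items():
            lines.append(
                f"- LD method (pcrit={pcrit}): Ne = {fmt(row['Ne'])} "
                f"[{fmt(row['ci'][0])}, {fmt(row['ci'][1])}]"
            )
        he = q["het_excess"]
        if he:
            lines.append(
                f"- heterozygote excess: Nb = {fmt(he['Nb'])} "
                f"[{fmt(he['ci'][0])}, {fmt(he['ci'][1])}]"
            )
    if "divergence" in stages and "t_years" in stages.get("divergence", {}):
        dvg = stages["divergence"]
        lines += [
            "",
            "## Divergence conversion",
            f"- t ≈ {fmt(dvg['t_years'])} years ({fmt(dvg['t_generations'])} "
            f"generations); female Ne ≈ {fmt(dvg['Ne_female'])}; "
            f"{fmt(dvg['migrants_per_generation'])} migrants/generation",
        ]
    if report.get("errors"):
        lines += ["", "## Stage failures"]
        for k, v in report["errors"].items():
            lines.append(f"- {k}: {v}")
    return "\n".join(lines) + "\n"
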