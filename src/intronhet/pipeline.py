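"""End-to-end orchestration of the simulated analysis.

``run_end_to_end`` executes the stages in dependency order on a synthetic
dataset: simulate -> methylation calling -> heterochromatic domains ->
intron/TE classification and enrichment -> premature-termination ratio
tests -> tissue specificity -> inter-species divergence.  Every tunable
threshold lives in :class:`PipelineConfig` with the analysis defaults
(coverage 3-100, >= 5 mCHG sites at mean >= 0.5 per domain, repeat
filters 100 bp / 70% / 20%, q <= 0.01, K_S <= 0.1, 80% structure
conservation).  A manifest of SHA-256 checksums makes reruns auditable:
the same config and seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    core_io,
    domains as domains_mod,
    methylation,
    ratio_test as ratio_mod,
    stats as stats_mod,
    synthetic_data as synth,
    te_overlap,
    evolution as evo,
)

ALL_STAGES = (
    "simulate", "methylation", "domains", "enrichment",
    "ratio_test", "specificity", "evolution",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # simulation scale
    n_genes: int = 200
    te_density: float = 0.3
    depth_mean: float = 20.0
    conversion_rate: float = 0.995
    n_reps: int = 2
    n_termination_effects: int = 20
    termination_fold: float = 10.0
    n_expression_conditions: int = 12
    ortholog_codons: int = 100
    ortholog_genes_per_group: int = 60
    dnds_het: float = 0.47
    dnds_normal: float = 0.38
    ortholog_ks: float = 0.05
    intron_rate_het: float = 0.0325
    intron_rate_normal: float = 0.0242
    # analysis thresholds (defaults = printed study values)
    min_coverage: int = 3
    max_coverage: int = 100
    call_fdr: float = 0.05
    domain_min_sites: int = 5
    domain_min_mean: float = 0.5
    repeat_min_length: int = 100
    repeat_min_coverage: float = 0.70
    repeat_max_divergence: float = 0.20
    ratio_q_threshold: float = 0.01
    ks_max: float = 0.1
    structure_conservation: float = 0.8
    n_perm: int = 10_000

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.min_coverage < 0 or self.max_coverage < self.min_coverage:
            raise ValueError("invalid coverage bounds")
        for name in ("call_fdr", "ratio_q_threshold", "domain_min_mean",
                     "repeat_min_coverage", "repeat_max_divergence",
                     "structure_conservation"):
            value = getattr(self, name)
            if not 0 <= value <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.n_perm < 1 or self.n_genes < 1:
            raise ValueError("n_perm and n_genes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        config = cls(**payload)
        config.validate()
        return config

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["stages"] = list(payload["stages"])
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sanitize(obj):
    """Replace non-finite floats with None so the JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(
        json.dumps(_sanitize(payload), indent=1, sort_keys=True, allow_nan=False)
        + "\n"
    )


def _stage_seeds(seed: int) -> dict[str, int]:
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, 2**31 - 1, size=len(ALL_STAGES) + 2)
    return {stage: int(draws[i]) for i, stage in enumerate(ALL_STAGES)} | {
        "counts_b": int(draws[-2]), "expression": int(draws[-1])
    }


def run_end_to_end(config: PipelineConfig, outdir: str | Path) -> dict[str, str]:
    """Run the configured stages and return {relative path: sha256}."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    config.to_yaml(out / "config.yaml")
    artifacts: list[Path] = [out / "config.yaml"]

    # --- simulate -----------------------------------------------------
    genes, repeats, truth = synth.simulate_annotation(
        n_genes=config.n_genes, te_density=config.te_density,
        seed=seeds["simulate"],
    )
    introns = core_io.derive_introns(genes)
    rng = np.random.default_rng(seeds["simulate"])
    het_genes_true = sorted(truth.heterochromatic_gene_ids)
    n_eff = min(config.n_termination_effects, len(het_genes_true))
    for gene_id in rng.choice(het_genes_true, size=n_eff, replace=False):
        truth.termination_effects[str(gene_id)] = config.termination_fold

    if "simulate" in config.stages:
        core_io.write_gff3(genes, out / "genes.gff3")
        core_io.write_bed(
            repeats.assign(name=repeats["family"], score=repeats["is_te"].astype(int))[
                ["chrom", "start", "end", "name", "score", "strand"]
            ],
            out / "repeats.bed",
        )
        truth.to_json(out / "truth.json")
        artifacts += [out / "genes.gff3", out / "repeats.bed", out / "truth.json"]

    sites = synth.simulate_methylome(
        genes, truth, repeats, depth_mean=config.depth_mean,
        conversion_rate=config.conversion_rate, seed=seeds["methylation"],
    )
    if "simulate" in config.stages:
        core_io.write_cytosine_report(sites, out / "cytosine_report.tsv")
        artifacts.append(out / "cytosine_report.tsv")

    # --- methylation calling -----------------------------------------
    control = sites[sites["chrom"] == synth.CONTROL_CONTIG]
    genome_sites = sites[sites["chrom"] != synth.CONTROL_CONTIG]
    conversion = methylation.estimate_conversion_rate(
        methylation.filter_coverage(control, config.min_coverage, config.max_coverage)
    )
    calls = methylation.call_methylcytosines(
        methylation.filter_coverage(genome_sites, config.min_coverage, config.max_coverage),
        conversion, config.call_fdr,
    )
    if "methylation" in config.stages:
        core_io.write_tsv(calls, out / "methylation_calls.tsv")
        artifacts.append(out / "methylation_calls.tsv")

    # --- domains and intron classification ---------------------------
    chg = calls[calls["context"] == "CHG"].reset_index(drop=True)
    domains = domains_mod.find_heterochromatic_domains(
        chg, config.domain_min_sites, config.domain_min_mean
    )
    domains_mod.classify_heterochromatic_introns(introns, domains)
    te_overlap.flag_intron_te_repeat_overlap(introns, repeats)
    if "domains" in config.stages:
        core_io.write_bed(domains_mod.domains_to_bed(domains), out / "domains.bed")
        intron_bed = core_io.introns_to_bed(introns)
        intron_bed["score"] = [int(i.heterochromatic) for i in introns]
        core_io.write_bed(intron_bed, out / "introns.bed")
        artifacts += [out / "domains.bed", out / "introns.bed"]

    # --- enrichment: position bias, venn, TE classes ------------------
    if "enrichment" in config.stages:
        het_ordinals = [i.ordinal for i in introns if i.heterochromatic]
        stats_payload: dict = {
            "conversion_rate": conversion,
            "n_domains": int(len(domains)),
            "n_heterochromatic_introns": int(len(het_ordinals)),
            "venn": te_overlap.venn_het_intron_te_repeat(introns),
        }
        if het_ordinals:
            dist = domains_mod.intron_position_distribution(introns)
            het_dist = domains_mod.intron_position_distribution(
                [i for i in introns if i.heterochromatic]
            )
            perm = stats_mod.positional_permutation_test(
                het_ordinals, [i.ordinal for i in introns],
                n_perm=config.n_perm, seed=seeds["enrichment"],
            )
            stats_payload.update(
                {
                    "mean_ordinal_all": dist.mean_ordinal,
                    "mean_ordinal_het": het_dist.mean_ordinal,
                    "position_permutation_p": perm.p_value,
                }
            )
        te_classes = te_overlap.classify_te_locations(
            repeats[repeats["is_te"]], genes
        )
        stats_payload["te_location_classes"] = (
            te_classes.value_counts().sort_index().to_dict()
        )
        _write_json(stats_payload, out / "enrichment.json")
        artifacts.append(out / "enrichment.json")

    # --- ratio test (two independent comparisons) ---------------------
    if "ratio_test" in config.stages:
        intron_ids = [i.intron_id for i in introns]
        effects = synth.termination_effects_by_intron(truth, introns)
        results = {}
        for name, count_seed in (
            ("comparison_a", seeds["ratio_test"]), ("comparison_b", seeds["counts_b"]),
        ):
            counts = synth.simulate_intron_counts(
                intron_ids, effects, n_reps=config.n_reps, seed=count_seed
            )
            res = ratio_mod.pre_post_ratio_glm_test(
                counts, "wt", "mut", q_threshold=config.ratio_q_threshold
            )
            core_io.write_tsv(res, out / f"ratio_{name}.tsv")
            artifacts.append(out / f"ratio_{name}.tsv")
            results[name] = res
        deg = ratio_mod.call_degs_and_intersect(
            results,
            {i.intron_id: i.gene_id for i in introns},
            domains_mod.heterochromatic_gene_ids(introns),
            {g.gene_id for g in genes},
        )
        _write_json(
            {
                "deg_counts": {k: len(v) for k, v in deg["deg_sets"].items()},
                "intersection_size": len(deg["intersection"]),
                "het_enrichment_p": deg["het_enrichment_p"],
                "het_enrichment_odds_ratio": deg["het_enrichment_odds_ratio"],
            },
            out / "deg_summary.json",
        )
        artifacts.append(out / "deg_summary.json")

    # --- specificity ---------------------------------------------------
    if "specificity" in config.stages:
        expr, expr_truth = synth.simulate_expression_atlas(
            n_genes=config.n_genes, n_conditions=config.n_expression_conditions,
            seed=seeds["expression"],
        )
        table = stats_mod.specificity_table(expr)
        table["true_class"] = table["gene_id"].map(expr_truth.specificity_class)
        core_io.write_tsv(table, out / "specificity.tsv")
        spec = table.loc[table["true_class"] == "specific", "entropy"]
        broad = table.loc[table["true_class"] == "broad", "entropy"]
        _write_json(
            {
                "mean_entropy_specific": float(spec.mean()),
                "mean_entropy_broad": float(broad.mean()),
                "effect_size_r": stats_mod.wilcoxon_effect_size(spec, broad),
            },
            out / "specificity_summary.json",
        )
        artifacts += [out / "specificity.tsv", out / "specificity_summary.json"]

    # --- evolution -----------------------------------------------------
    if "evolution" in config.stages:
        het_pairs, _ = synth.simulate_ortholog_pairs(
            n_genes=config.ortholog_genes_per_group,
            codons_per_gene=config.ortholog_codons,
            dnds=config.dnds_het, ks_target=config.ortholog_ks,
            intron_rate=config.intron_rate_het,
            seed=seeds["evolution"], gene_prefix="het",
        )
        normal_pairs, _ = synth.simulate_ortholog_pairs(
            n_genes=config.ortholog_genes_per_group,
            codons_per_gene=config.ortholog_codons,
            dnds=config.dnds_normal, ks_target=config.ortholog_ks,
            intron_rate=config.intron_rate_normal,
            seed=seeds["evolution"] + 1, gene_prefix="norm",
        )
        div = evo.divergence_table(het_pairs + normal_pairs)
        div = evo.ks_filter(div, config.ks_max)
        labels = pd.Series(
            ["het" if g.startswith("het") else "normal" for g in div["gene_id"]],
            index=div["gene_id"].to_numpy(),
        )
        summary = evo.group_rate_summary(div, labels)
        core_io.write_tsv(div, out / "divergence.tsv")
        core_io.write_tsv(summary, out / "divergence_groups.tsv")
        het_vals = div.loc[div["gene_id"].str.startswith("het"), ["K_A", "K_S"]].to_numpy()
        norm_vals = div.loc[div["gene_id"].str.startswith("norm"), ["K_A", "K_S"]].to_numpy()
        perm = evo.group_permutation_test(
            het_vals, norm_vals, n_perm=config.n_perm,
            seed=seeds["evolution"], statistic="kaks_diff",
        )
        _write_json(
            {"kaks_permutation_p": perm.p_value, "kaks_diff_observed": perm.observed},
            out / "evolution_summary.json",
        )
        artifacts += [
            out / "divergence.tsv", out / "divergence_groups.tsv",
            out / "evolution_summary.json",
        ]

    manifest = {p.relative_to(out).as_posix(): _sha256(p) for p in artifacts}
    _write_json(manifest, out / "manifest.json")
    return manifest
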