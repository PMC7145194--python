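import numpy as np
import pandas as pd
import pytest

from intronhet.core_io import derive_introns, read_cytosine_report, read_gff3, write_cytosine_report, write_gff3
from intronhet.evolution import divergence_table
from intronhet.stats import roku_entropy
from intronhet.synthetic_data import (
    GenerationError,
    SimulationTruth,
    simulate_annotation,
    simulate_expression_atlas,
    simulate_intron_counts,
    simulate_methylome,
    simulate_ortholog_pairs,
    termination_effects_by_intron,
    write_ortholog_alignments,
    read_ortholog_alignments,
)


class TestAnnotation:
    def test_single_gene_no_introns(self):
        genes, repeats, truth = simulate_annotation(
            n_genes=1, introns_per_gene_range=(0, 0), te_density=0.5,
            intergenic_te_prob=0.0, repeat_density=0.0, seed=0,
        )
        assert len(genes) == 1
        assert len(genes[0].transcripts[0].exons) == 1
        assert len(repeats) == 0
        assert truth.heterochromatic_intron_ids == set()

    def test_same_seed_reproduces_identical_files(self, tmp_path):
        for run in ("a", "b"):
            genes, repeats, truth = simulate_annotation(n_genes=30, seed=11)
            write_gff3(genes, tmp_path / f"{run}.gff3")
            truth.to_json(tmp_path / f"{run}.json")
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()

    def test_te_density_recovered_within_three_binomial_se(self):
        density = 0.3
        genes, _, truth = simulate_annotation(
            n_genes=2000, te_density=density, seed=5
        )
        observed = len(truth.heterochromatic_gene_ids) / len(genes)
        se = np.sqrt(density * (1 - density) / len(genes))
        assert abs(observed - density) < 3 * se

    def test_truth_ids_exist_in_annotation(self):
        genes, _, truth = simulate_annotation(n_genes=100, seed=2)
        intron_ids = {i.intron_id for i in derive_introns(genes)}
        assert truth.heterochromatic_intron_ids <= intron_ids

    def test_heterochromatic_ordinals_are_five_prime_biased(self):
        genes, _, truth = simulate_annotation(n_genes=2000, seed=3)
        het_ordinals = [int(i.rsplit(":", 1)[1]) for i in truth.heterochromatic_intron_ids]
        all_ordinals = [i.ordinal for i in derive_introns(genes)]
        assert np.mean(het_ordinals) < np.mean(all_ordinals)

    def test_impossible_geometry_raises(self):
        with pytest.raises(GenerationError):
            simulate_annotation(
                n_genes=5, te_intron_length_range=(300, 400),
                te_length_range=(350, 500), seed=0,
            )

    def test_generated_annotation_parses_through_core_io(self, tmp_path):
        genes, _, _ = simulate_annotation(n_genes=20, seed=7)
        write_gff3(genes, tmp_path / "x.gff3")
        back = read_gff3(tmp_path / "x.gff3")
        assert [g.gene_id for g in back] == [g.gene_id for g in genes]
        assert all(
            a.transcripts[0].exons == b.transcripts[0].exons
            for a, b in zip(back, genes)
        )


class TestMethylome:
    def test_deterministic_for_fixed_seed(self):
        genes, repeats, truth = simulate_annotation(n_genes=10, seed=1)
        a = simulate_methylome(genes, truth, repeats, seed=4)
        b = simulate_methylome(genes, truth, repeats, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_depth_warns_and_returns_empty(self):
        genes, repeats, truth = simulate_annotation(n_genes=5, seed=1)
        with pytest.warns(UserWarning):
            out = simulate_methylome(genes, truth, repeats, depth_mean=0)
        assert len(out) == 0

    def test_perfect_conversion_all_euchromatic_zero_levels_gives_no_meth(self):
        genes, repeats, truth = simulate_annotation(
            n_genes=5, te_density=0.0, seed=1
        )
        out = simulate_methylome(
            genes, SimulationTruth(), repeats, conversion_rate=1.0,
            level_params={"CG": (0.0, 0.0), "CHG": (0.0, 0.0), "CHH": (0.0, 0.0)},
            seed=2,
        )
        assert (out["n_meth"] == 0).all()

    def test_heterochromatic_regions_show_high_chg(self):
        genes, repeats, truth = simulate_annotation(n_genes=60, seed=6)
        sites = simulate_methylome(genes, truth, repeats, seed=8)
        introns = {i.intron_id: i for i in derive_introns(genes)}
        levels = []
        for iid in truth.heterochromatic_intron_ids:
            intron = introns[iid]
            sub = sites[
                (sites["chrom"] == intron.chrom)
                & (sites["pos"] >= intron.start) & (sites["pos"] < intron.end)
                & (sites["context"] == "CHG")
                & (sites["n_meth"] + sites["n_unmeth"] > 0)
            ]
            levels.append(
                (sub["n_meth"] / (sub["n_meth"] + sub["n_unmeth"])).mean()
            )
        # the TE-anchored core is highly methylated; the intron-wide mean
        # dilutes it with euchromatic flanks, so expect clearly elevated
        # but not core-level methylation
        assert np.mean(levels) > 0.15

    def test_report_round_trips_through_core_io(self, tmp_path):
        genes, repeats, truth = simulate_annotation(n_genes=5, seed=1)
        sites = simulate_methylome(genes, truth, repeats, seed=2)
        write_cytosine_report(sites, tmp_path / "r.tsv")
        back = read_cytosine_report(tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back, sites)

    def test_control_contig_present_for_conversion_estimation(self):
        genes, repeats, truth = simulate_annotation(n_genes=5, seed=1)
        sites = simulate_methylome(genes, truth, repeats, seed=2)
        control = sites[sites["chrom"] == "control_chloroplast"]
        assert len(control) == 2500
        # control is unmethylated: observed level ~ (1 - conversion) = 0.005
        level = control["n_meth"].sum() / (control["n_meth"] + control["n_unmeth"]).sum()
        assert level < 0.02


class TestIntronCounts:
    def test_no_effects_means_equal_in_expectation(self):
        ids = [f"i{k}" for k in range(500)]
        counts = simulate_intron_counts(ids, {}, seed=0)
        by_geno = counts.groupby("genotype")[["pre_count", "post_count"]].mean()
        ratio = by_geno.loc["mut", "post_count"] / by_geno.loc["wt", "post_count"]
        assert 0.9 < ratio < 1.1

    def test_tenfold_effect_reduces_mutant_post_mean(self):
        ids = ["hit"] * 1  # single intron, many reps to average
        counts = simulate_intron_counts(
            ids, {"hit": 10.0}, depth_mean=100, n_reps=200, seed=1,
            expression_sigma=0.0,
        )
        mut = counts[counts["genotype"] == "mut"]
        wt = counts[counts["genotype"] == "wt"]
        assert mut["post_count"].mean() == pytest.approx(10, rel=0.3)
        assert wt["post_count"].mean() == pytest.approx(100, rel=0.15)
        assert mut["pre_count"].mean() == pytest.approx(100, rel=0.15)

    def test_effect_mapping_targets_heterochromatic_introns(self):
        genes, _, truth = simulate_annotation(n_genes=50, seed=2)
        introns = derive_introns(genes)
        gene = sorted(truth.heterochromatic_gene_ids)[0]
        truth.termination_effects[gene] = 10.0
        effects = termination_effects_by_intron(truth, introns)
        assert all(i.startswith(gene) for i in effects)
        assert set(effects) <= truth.heterochromatic_intron_ids

    def test_deterministic(self):
        ids = [f"i{k}" for k in range(50)]
        a = simulate_intron_counts(ids, {"i0": 5.0}, seed=3)
        b = simulate_intron_counts(ids, {"i0": 5.0}, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestExpressionAtlas:
    def test_specific_fraction_zero_means_all_broad(self):
        _, truth = simulate_expression_atlas(n_genes=50, specific_fraction=0.0, seed=0)
        assert set(truth.specificity_class.values()) == {"broad"}

    def test_entropy_separates_classes(self):
        expr, truth = simulate_expression_atlas(n_genes=200, seed=1)
        h = expr.apply(lambda row: roku_entropy(row.to_numpy()), axis=1)
        labels = pd.Series(truth.specificity_class)
        spec = h[labels == "specific"]
        broad = h[labels == "broad"]
        assert spec.mean() < 1.0
        assert broad.mean() > np.log2(expr.shape[1]) - 1.0
        # ranking by entropy separates the classes almost perfectly
        from scipy.stats import mannwhitneyu

        u = mannwhitneyu(broad, spec, alternative="greater").statistic
        auc = u / (len(spec) * len(broad))
        assert auc > 0.95

    def test_condition_count_validated(self):
        with pytest.raises(GenerationError):
            simulate_expression_atlas(n_conditions=1)


class TestOrthologPairs:
    def test_zero_dnds_gives_zero_ka(self):
        pairs, _ = simulate_ortholog_pairs(
            n_genes=20, codons_per_gene=100, dnds=0.0, ks_target=0.05, seed=0
        )
        div = divergence_table(pairs)
        assert (div["K_A"] == 0).all()
        assert div["K_S"].mean() > 0

    def test_zero_intron_rate_gives_zero_ki(self):
        pairs, _ = simulate_ortholog_pairs(
            n_genes=10, intron_rate=0.0, masked_rate_multiplier=0.0, seed=1
        )
        div = divergence_table(pairs)
        assert (div["mean_K_I"] == 0).all()

    def test_no_internal_stop_codons(self):
        from Bio.Seq import Seq

        pairs, _ = simulate_ortholog_pairs(n_genes=10, codons_per_gene=50, seed=2)
        for p in pairs:
            assert "*" not in str(Seq(p.cds1).translate())
            assert "*" not in str(Seq(p.cds2).translate())

    def test_ks_target_out_of_range_raises(self):
        with pytest.raises(GenerationError):
            simulate_ortholog_pairs(ks_target=0.5)

    def test_alignment_files_round_trip(self, tmp_path):
        pairs, _ = simulate_ortholog_pairs(n_genes=5, codons_per_gene=20, seed=3)
        write_ortholog_alignments(
            pairs, tmp_path / "cds.fa", tmp_path / "introns.fa", tmp_path / "mask.fa"
        )
        back = read_ortholog_alignments(
            tmp_path / "cds.fa", tmp_path / "introns.fa", tmp_path / "mask.fa"
        )
        assert [p.gene_id for p in back] == [p.gene_id for p in pairs]
        for a, b in zip(back, pairs):
            assert a.cds1 == b.cds1 and a.cds2 == b.cds2
            for (s1a, s2a, ma), (s1b, s2b, mb) in zip(a.introns, b.introns):
                assert s1a == s1b and s2a == s2b
                assert (ma == mb).all()

    def test_masked_columns_hypermutate(self):
        pairs, _ = simulate_ortholog_pairs(
            n_genes=40, intron_rate=0.03, masked_rate_multiplier=5.0, seed=4
        )
        masked_diffs = unmasked_diffs = masked_n = unmasked_n = 0
        for p in pairs:
            for s1, s2, mask in p.introns:
                diff = np.array([a != b for a, b in zip(s1, s2)])
                masked_diffs += diff[mask].sum()
                masked_n += mask.sum()
                unmasked_diffs += diff[~mask].sum()
                unmasked_n += (~mask).sum()
        assert masked_diffs / masked_n > 3 * (unmasked_diffs / unmasked_n)
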