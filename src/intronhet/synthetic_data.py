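"""Synthetic annotation, methylome, count, expression and ortholog data.

Every generator is a pure function of its parameters and seed, and every
generated file parses back through :mod:`intronhet.core_io`.  Ground truth
(which introns are heterochromatic, which genes carry a termination
effect, true divergence rates, true specificity classes) is carried in a
:class:`SimulationTruth` sidecar so downstream recovery can be scored.

What is emulated: beta-binomial per-site methylation with context-specific
levels and bisulfite non-conversion (including an unmethylated control
contig named ``control_chloroplast``), negative-binomial pre/post-intron
read counts with genotype-specific termination effects, expression
atlases with controllable tissue specificity, and ortholog codon/intron
alignments diverging at specified synonymous, nonsynonymous and intronic
rates with hyper-mutated repeat-masked blocks.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    CYTOSINE_COLUMNS,
    GeneModel,
    IntronRecord,
    TranscriptModel,
    derive_introns,
)
from .evolution import NUCLEOTIDES, OrthologAlignmentPair, _build_codon_table

DEFAULT_LEVEL_PARAMS: dict[str, tuple[float, float]] = {
    # context -> (heterochromatic mean, euchromatic mean)
    "CG": (0.90, 0.05),
    "CHG": (0.60, 0.02),
    "CHH": (0.10, 0.01),
}

CONTROL_CONTIG = "control_chloroplast"


class GenerationError(ValueError):
    pass


@dataclass
class SimulationTruth:
    heterochromatic_intron_ids: set[str] = field(default_factory=set)
    termination_effects: dict[str, float] = field(default_factory=dict)  # gene -> fold
    true_dnds: dict[str, float] = field(default_factory=dict)
    true_intron_rate: dict[str, float] = field(default_factory=dict)
    specificity_class: dict[str, str] = field(default_factory=dict)

    @property
    def heterochromatic_gene_ids(self) -> set[str]:
        return {i.split(":", 1)[0] for i in self.heterochromatic_intron_ids}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "heterochromatic_intron_ids": sorted(self.heterochromatic_intron_ids),
            "termination_effects": dict(sorted(self.termination_effects.items())),
            "true_dnds": dict(sorted(self.true_dnds.items())),
            "true_intron_rate": dict(sorted(self.true_intron_rate.items())),
            "specificity_class": dict(sorted(self.specificity_class.items())),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            heterochromatic_intron_ids=set(payload["heterochromatic_intron_ids"]),
            termination_effects=payload["termination_effects"],
            true_dnds=payload["true_dnds"],
            true_intron_rate=payload["true_intron_rate"],
            specificity_class=payload["specificity_class"],
        )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def simulate_annotation(
    n_genes: int = 200,
    introns_per_gene_range: tuple[int, int] = (1, 8),
    te_density: float = 0.3,
    seed: int = 0,
    exon_length_range: tuple[int, int] = (100, 300),
    intron_length_range: tuple[int, int] = (150, 400),
    te_intron_length_range: tuple[int, int] = (600, 1000),
    te_length_range: tuple[int, int] = (250, 400),
    te_offset: int = 100,
    repeat_density: float = 0.10,
    intergenic_te_prob: float = 0.3,
    ordinal_bias: float = 0.45,
    genes_per_chrom: int = 100,
) -> tuple[list[GeneModel], pd.DataFrame, SimulationTruth]:
    """Generate gene models with TE-bearing (future heterochromatic) introns.

    ``te_density`` is the fraction of multi-intron genes that receive a TE
    inside one intron; the host intron's ordinal is drawn from a truncated
    geometric distribution with success probability ``ordinal_bias``, so
    promoter-proximal introns are favoured.  A fraction ``repeat_density``
    of genes receives a non-TE simple repeat in a random intron, and each
    sufficiently large intergenic gap hosts an intergenic TE with
    probability ``intergenic_te_prob``.  Returns (gene models, repeat
    table with an ``is_te`` column, truth).
    """
    if n_genes < 1:
        raise GenerationError("n_genes must be >= 1")
    lo, hi = introns_per_gene_range
    if lo < 0 or hi < lo:
        raise GenerationError("invalid introns_per_gene_range")
    if te_intron_length_range[0] < te_length_range[1] + 2 * te_offset:
        raise GenerationError(
            "TE-hosting introns too short for the largest TE plus offsets: "
            f"{te_intron_length_range} vs {te_length_range} + 2x{te_offset}"
        )
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    repeat_rows: list[tuple] = []
    truth = SimulationTruth()

    cursor: dict[str, int] = {}
    for g in range(n_genes):
        chrom = f"chr{g // genes_per_chrom + 1}"
        pos = cursor.get(chrom, 0)
        gap = int(rng.integers(300, 801))
        if rng.random() < intergenic_te_prob and gap >= te_length_range[1] + 100:
            te_len = int(rng.integers(te_length_range[0], te_length_range[1] + 1))
            te_start = pos + 50
            repeat_rows.append(
                (chrom, te_start, te_start + te_len,
                 "+" if rng.random() < 0.5 else "-", "TE_intergenic", True)
            )
        pos += gap
        gene_id = f"g{g + 1:05d}"
        tx_id = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = int(rng.integers(lo, hi + 1))

        has_te = n_introns > 0 and rng.random() < te_density
        te_ordinal = None
        if has_te:
            te_ordinal = min(int(rng.geometric(ordinal_bias)), n_introns)
        has_repeat = n_introns > 0 and rng.random() < repeat_density
        repeat_ordinal = int(rng.integers(1, n_introns + 1)) if has_repeat else None

        # genomic order of ordinals depends on strand
        exon_lens = rng.integers(
            exon_length_range[0], exon_length_range[1] + 1, size=n_introns + 1
        )
        intron_specs = []  # genomic order: (length, ordinal)
        for k in range(n_introns):
            ordinal = k + 1 if strand == "+" else n_introns - k
            if te_ordinal is not None and ordinal == te_ordinal:
                length = int(rng.integers(*te_intron_length_range))
            else:
                length = int(rng.integers(*intron_length_range))
            intron_specs.append((length, ordinal))

        exons = []
        p = pos
        for k in range(n_introns + 1):
            exons.append((p, p + int(exon_lens[k])))
            p += int(exon_lens[k])
            if k < n_introns:
                length, ordinal = intron_specs[k]
                istart, iend = p, p + length
                if te_ordinal is not None and ordinal == te_ordinal:
                    te_len = int(rng.integers(te_length_range[0], te_length_range[1] + 1))
                    offset = int(rng.integers(te_offset, length - te_len - te_offset + 1))
                    repeat_rows.append(
                        (chrom, istart + offset, istart + offset + te_len,
                         "+" if rng.random() < 0.5 else "-", "TE_intronic", True)
                    )
                    truth.heterochromatic_intron_ids.add(
                        f"{gene_id}:{tx_id}:{ordinal}"
                    )
                if repeat_ordinal is not None and ordinal == repeat_ordinal:
                    rep_len = int(rng.integers(50, min(150, length - 40)))
                    repeat_rows.append(
                        (chrom, istart + 10, istart + 10 + rep_len,
                         "+", "Simple_repeat", False)
                    )
                p = iend
        cursor[chrom] = p
        gene = GeneModel(gene_id, chrom, strand, (TranscriptModel(tx_id, tuple(exons)),))
        gene.validate()
        genes.append(gene)

    repeats = pd.DataFrame(
        repeat_rows, columns=["chrom", "start", "end", "strand", "family", "is_te"]
    ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genes, repeats, truth


# ---------------------------------------------------------------------------
# Methylome
# ---------------------------------------------------------------------------

def _interval_lookup(intervals: list[tuple[int, int]]):
    starts = np.array([s for s, _ in intervals]) if intervals else np.empty(0)
    ends = np.array([e for _, e in intervals]) if intervals else np.empty(0)

    def contains(pos: np.ndarray) -> np.ndarray:
        if starts.size == 0:
            return np.zeros(pos.size, dtype=bool)
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.size, dtype=bool)
        hit[ok] = pos[ok] < ends[idx[ok]]
        return hit

    return contains


def simulate_methylome(
    genes: Sequence[GeneModel],
    truth: SimulationTruth,
    repeats: pd.DataFrame | None = None,
    depth_mean: float = 20.0,
    conversion_rate: float = 0.995,
    level_params: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    spacing_range: tuple[int, int] = (10, 60),
    concentration: float = 20.0,
    flank: int = 200,
    control_sites: int = 2500,
    spread: int = 40,
    intron_margin: int = 60,
) -> pd.DataFrame:
    """Beta-binomial per-site methylation counts over the simulated genome.

    Cytosine sites of each context are laid down independently at uniform
    10-60 bp spacing over every chromosome (gene bodies plus flanks and
    intergenic space).  Heterochromatin is anchored on the TE copies
    inside the truth heterochromatic introns: when ``repeats`` is given,
    the methylated region is each intronic TE expanded by ``spread`` bp
    and clipped to its intron; without a repeat table the whole intron
    minus ``intron_margin`` bp at each edge is used.  Sites in those
    regions draw their latent level from Beta distributions centred on
    the heterochromatic means; all others use the euchromatic means.
    Read depth is Poisson; bisulfite non-conversion adds methylated reads
    at unmethylated cytosines at rate (1 - conversion_rate).  An
    all-unmethylated control contig (``control_chloroplast``) is appended
    for conversion-rate estimation.
    """
    if not 0 < conversion_rate <= 1:
        raise GenerationError("conversion_rate must be in (0, 1]")
    params = dict(DEFAULT_LEVEL_PARAMS)
    if level_params:
        params.update(level_params)
    if depth_mean <= 0:
        warnings.warn("zero sequencing depth: empty cytosine report")
        return pd.DataFrame(columns=CYTOSINE_COLUMNS)

    rng = np.random.default_rng(seed)
    het_ids = truth.heterochromatic_intron_ids
    het_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for intron in derive_introns(genes):
        if intron.intron_id not in het_ids:
            continue
        region = None
        if repeats is not None:
            hosted = repeats[
                (repeats["chrom"] == intron.chrom)
                & (repeats["start"] >= intron.start)
                & (repeats["end"] <= intron.end)
                & repeats["is_te"].astype(bool)
            ]
            if len(hosted):
                region = (
                    max(intron.start, int(hosted["start"].min()) - spread),
                    min(intron.end, int(hosted["end"].max()) + spread),
                )
        if region is None:
            region = (intron.start + intron_margin, intron.end - intron_margin)
        if region[1] > region[0]:
            het_by_chrom.setdefault(intron.chrom, []).append(region)
    chrom_len: dict[str, int] = {}
    for gene in genes:
        chrom_len[gene.chrom] = max(chrom_len.get(gene.chrom, 0), gene.span[1] + flank)

    frames = []
    for chrom in sorted(chrom_len):
        length = chrom_len[chrom]
        lookup = _interval_lookup(sorted(het_by_chrom.get(chrom, [])))
        for context in ("CG", "CHG", "CHH"):
            n_approx = int(length / np.mean(spacing_range)) + 10
            gaps = rng.integers(spacing_range[0], spacing_range[1] + 1, size=n_approx)
            pos = np.cumsum(gaps)
            pos = pos[pos < length]
            het = lookup(pos)
            het_mean, euch_mean = params[context]
            mean = np.where(het, het_mean, euch_mean)
            a = mean * concentration
            b = (1 - mean) * concentration
            level = np.where(mean > 0, rng.beta(np.maximum(a, 1e-12), b), 0.0)
            depth = rng.poisson(depth_mean, size=pos.size)
            true_meth = rng.binomial(depth, level)
            nonconv = rng.binomial(depth - true_meth, 1 - conversion_rate)
            n_meth = true_meth + nonconv
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": pos,
                        "strand": np.where(rng.random(pos.size) < 0.5, "+", "-"),
                        "context": context,
                        "n_meth": n_meth,
                        "n_unmeth": depth - n_meth,
                    }
                )
            )
    # unmethylated control contig
    pos = np.arange(control_sites) * 20 + 10
    contexts = np.array(["CG", "CHG", "CHH"])[np.arange(control_sites) % 3]
    depth = rng.poisson(depth_mean, size=control_sites)
    n_meth = rng.binomial(depth, 1 - conversion_rate)
    frames.append(
        pd.DataFrame(
            {
                "chrom": CONTROL_CONTIG,
                "pos": pos,
                "strand": np.where(rng.random(control_sites) < 0.5, "+", "-"),
                "context": contexts,
                "n_meth": n_meth,
                "n_unmeth": depth - n_meth,
            }
        )
    )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos", "context"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Pre/post-intron counts
# ---------------------------------------------------------------------------

def simulate_intron_counts(
    intron_ids: Sequence[str],
    effects: Mapping[str, float],
    depth_mean: float = 100.0,
    dispersion: float = 10.0,
    n_reps: int = 2,
    seed: int = 0,
    genotypes: tuple[str, str] = ("wt", "mut"),
    expression_sigma: float = 0.5,
) -> pd.DataFrame:
    """Negative-binomial pre/post counts per intron, sample and genotype.

    ``effects`` maps intron ids to fold reductions applied to the
    post-intron mean in the second (mutant) genotype only.  Counts are
    gamma-Poisson (negative binomial marginally); the gamma expression
    factor is shared by the pre and post counts of one sample, because
    both are sampled from the same transcript pool — replicate-to-
    replicate expression noise moves them together, while the pre/post
    split within a sample stays binomial.  ``dispersion`` is the gamma
    shape (larger = less overdispersed).
    """
    if n_reps < 1:
        raise GenerationError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    control, mutant = genotypes
    n = len(intron_ids)
    base = depth_mean * rng.lognormal(0.0, expression_sigma, size=n)
    fold = np.array([effects.get(i, 1.0) for i in intron_ids], dtype=float)
    if (fold <= 0).any():
        raise GenerationError("effect folds must be positive")
    rows = []
    for genotype in (control, mutant):
        post_mean = base / fold if genotype == mutant else base
        for rep in range(1, n_reps + 1):
            factor = rng.gamma(dispersion, 1.0 / dispersion, size=n)
            pre = rng.poisson(base * factor)
            post = rng.poisson(post_mean * factor)
            rows.append(
                pd.DataFrame(
                    {
                        "intron_id": intron_ids,
                        "sample_id": f"{genotype}_{rep}",
                        "genotype": genotype,
                        "pre_count": pre,
                        "post_count": post,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def termination_effects_by_intron(
    truth: SimulationTruth, introns: Sequence[IntronRecord]
) -> dict[str, float]:
    """Map gene-level termination effects onto the genes' heterochromatic
    introns (the introns where premature termination would act)."""
    out: dict[str, float] = {}
    for intron in introns:
        fold = truth.termination_effects.get(intron.gene_id)
        if fold is not None and intron.intron_id in truth.heterochromatic_intron_ids:
            out[intron.intron_id] = fold
    return out


# ---------------------------------------------------------------------------
# Expression atlas
# ---------------------------------------------------------------------------

def simulate_expression_atlas(
    n_genes: int = 1000,
    n_conditions: int = 10,
    specific_fraction: float = 0.2,
    noise_sigma: float = 0.25,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Expression matrix with "specific" genes expressed in exactly one
    condition and "broad" genes near-uniform with multiplicative noise."""
    if n_conditions < 2:
        raise GenerationError("n_conditions must be >= 2")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    matrix = np.zeros((n_genes, n_conditions))
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    n_specific = int(round(specific_fraction * n_genes))
    for i in range(n_genes):
        if i < n_specific:
            cond = int(rng.integers(n_conditions))
            matrix[i, cond] = rng.lognormal(np.log(100), 0.3)
            truth.specificity_class[gene_ids[i]] = "specific"
        else:
            base = rng.lognormal(np.log(50), 0.3)
            matrix[i] = base * rng.lognormal(0.0, noise_sigma, size=n_conditions)
            truth.specificity_class[gene_ids[i]] = "broad"
    df = pd.DataFrame(
        matrix, index=gene_ids,
        columns=[f"cond_{j + 1}" for j in range(n_conditions)],
    )
    df.index.name = "gene_id"
    return df, truth


# ---------------------------------------------------------------------------
# Ortholog pairs
# ---------------------------------------------------------------------------

def _codon_mutation_tables():
    table = _build_codon_table()
    out = {}
    for codon, aa in table.items():
        if aa == "*":
            continue
        per_pos = []
        for pos in range(3):
            syn_alts, nonsyn_alts = [], []
            for base in NUCLEOTIDES:
                if base == codon[pos]:
                    continue
                alt = codon[:pos] + base + codon[pos + 1:]
                if table[alt] == "*":
                    continue
                (syn_alts if table[alt] == aa else nonsyn_alts).append(alt)
            valid = len(syn_alts) + len(nonsyn_alts)
            f = len(syn_alts) / valid if valid else 0.0
            per_pos.append((f, tuple(syn_alts), tuple(nonsyn_alts)))
        out[codon] = tuple(per_pos)
    return out


_MUTATION_TABLES: dict | None = None


def simulate_ortholog_pairs(
    n_genes: int = 500,
    codons_per_gene: int = 200,
    dnds: float = 0.4,
    ks_target: float = 0.05,
    intron_rate: float = 0.03,
    repeat_mask_fraction: float = 0.2,
    masked_rate_multiplier: float = 5.0,
    introns_per_gene: int = 1,
    intron_length: int = 300,
    structure_mismatch: float = 0.05,
    seed: int = 0,
    gene_prefix: str = "g",
) -> tuple[list[OrthologAlignmentPair], SimulationTruth]:
    """Ortholog alignment pairs with controlled divergence.

    Synonymous changes are placed so the expected Nei-Gojobori K_S equals
    ``ks_target`` and nonsynonymous changes so K_A / K_S equals ``dnds``:
    each codon position carries a synonymous difference with probability
    p_S x f (f = fraction of synonymous single-nucleotide changes at that
    position) and a nonsynonymous one with probability p_N x (1 - f),
    where p_S / p_N invert the Jukes-Cantor correction of K_S / K_A.
    Internal stop codons are never emitted.  Intron rows diverge at
    ``intron_rate`` per unmasked column; a contiguous repeat-masked block
    (fraction ``repeat_mask_fraction``) mutates ``masked_rate_multiplier``
    times faster and must be excluded by the estimator.
    """
    global _MUTATION_TABLES
    if not 0 < ks_target <= 0.1:
        raise GenerationError("ks_target must be in (0, 0.1]")
    if dnds < 0:
        raise GenerationError("dnds must be >= 0")
    if _MUTATION_TABLES is None:
        _MUTATION_TABLES = _codon_mutation_tables()
    tables = _MUTATION_TABLES
    sense_codons = sorted(tables)
    rng = np.random.default_rng(seed)
    p_s = 0.75 * (1 - np.exp(-4 * ks_target / 3))
    p_n = 0.75 * (1 - np.exp(-4 * ks_target * dnds / 3))
    masked_rate = min(0.7, intron_rate * masked_rate_multiplier)

    pairs: list[OrthologAlignmentPair] = []
    truth = SimulationTruth()
    for g in range(n_genes):
        gene_id = f"{gene_prefix}{g + 1:05d}"
        codons1, codons2 = [], []
        for _ in range(codons_per_gene):
            codon = sense_codons[rng.integers(len(sense_codons))]
            mutant = codon
            for pos in range(3):
                f, syn_alts, nonsyn_alts = tables[mutant][pos]
                u = rng.random()
                if syn_alts and u < p_s * f:
                    mutant = syn_alts[rng.integers(len(syn_alts))]
                elif nonsyn_alts and u < p_s * f + p_n * (1 - f):
                    mutant = nonsyn_alts[rng.integers(len(nonsyn_alts))]
            codons1.append(codon)
            codons2.append(mutant)
        cds1, cds2 = "".join(codons1), "".join(codons2)

        introns = []
        for _ in range(introns_per_gene):
            bases = rng.integers(4, size=intron_length)
            seq1 = np.array(list(NUCLEOTIDES))[bases]
            n_masked = int(round(repeat_mask_fraction * intron_length))
            mask = np.zeros(intron_length, dtype=bool)
            mask[:n_masked] = True
            rate = np.where(mask, masked_rate, intron_rate)
            mutate = rng.random(intron_length) < rate
            shift = rng.integers(1, 4, size=intron_length)
            seq2 = np.array(list(NUCLEOTIDES))[(bases + shift) % 4]
            seq2 = np.where(mutate, seq2, seq1)
            introns.append(("".join(seq1), "".join(seq2), mask))

        n_cols = 3 * codons_per_gene + introns_per_gene * intron_length
        states1 = "E" * (3 * codons_per_gene) + "I" * (introns_per_gene * intron_length)
        flip = rng.random(n_cols) < structure_mismatch
        states2 = "".join(
            ("I" if s == "E" else "E") if f else s for s, f in zip(states1, flip)
        )
        pairs.append(
            OrthologAlignmentPair(
                gene_id=gene_id,
                cds1=cds1,
                cds2=cds2,
                introns=tuple(introns),
                states1=states1,
                states2=states2,
            )
        )
        truth.true_dnds[gene_id] = dnds
        truth.true_intron_rate[gene_id] = intron_rate
    return pairs, truth


# ---------------------------------------------------------------------------
# Alignment serialization (aligned FASTA + 0/1 mask FASTA)
# ---------------------------------------------------------------------------

def write_ortholog_alignments(
    pairs: Sequence[OrthologAlignmentPair], cds_path: str | Path,
    intron_path: str | Path, mask_path: str | Path,
) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    cds_records, intron_records, mask_records = [], [], []
    for pair in pairs:
        cds_records.append(SeqRecord(Seq(pair.cds1), id=f"{pair.gene_id}|sp1", description=""))
        cds_records.append(SeqRecord(Seq(pair.cds2), id=f"{pair.gene_id}|sp2", description=""))
        for k, (s1, s2, mask) in enumerate(pair.introns, start=1):
            intron_records.append(
                SeqRecord(Seq(s1), id=f"{pair.gene_id}|intron{k}|sp1", description="")
            )
            intron_records.append(
                SeqRecord(Seq(s2), id=f"{pair.gene_id}|intron{k}|sp2", description="")
            )
            mask_records.append(
                SeqRecord(
                    Seq("".join("1" if m else "0" for m in mask)),
                    id=f"{pair.gene_id}|intron{k}", description="",
                )
            )
    SeqIO.write(cds_records, str(cds_path), "fasta")
    SeqIO.write(intron_records, str(intron_path), "fasta")
    SeqIO.write(mask_records, str(mask_path), "fasta")


def read_ortholog_alignments(
    cds_path: str | Path, intron_path: str | Path, mask_path: str | Path
) -> list[OrthologAlignmentPair]:
    from Bio import SeqIO

    cds: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(cds_path), "fasta"):
        gene, sp = rec.id.split("|")
        cds.setdefault(gene, {})[sp] = str(rec.seq)
    introns: dict[str, dict[str, dict[str, str]]] = {}
    for rec in SeqIO.parse(str(intron_path), "fasta"):
        gene, intron, sp = rec.id.split("|")
        introns.setdefault(gene, {}).setdefault(intron, {})[sp] = str(rec.seq)
    masks: dict[str, dict[str, np.ndarray]] = {}
    for rec in SeqIO.parse(str(mask_path), "fasta"):
        gene, intron = rec.id.split("|")
        masks.setdefault(gene, {})[intron] = np.array(
            [c == "1" for c in str(rec.seq)], dtype=bool
        )
    pairs = []
    for gene in sorted(cds):
        intron_tuples = tuple(
            (introns[gene][k]["sp1"], introns[gene][k]["sp2"], masks[gene][k])
            for k in sorted(introns.get(gene, {}))
        )
        pairs.append(
            OrthologAlignmentPair(
                gene_id=gene, cds1=cds[gene]["sp1"], cds2=cds[gene]["sp2"],
                introns=intron_tuples,
            )
        )
    return pairs
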