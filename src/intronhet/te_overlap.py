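"""TE/repeat hit filtering, genomic location taxonomy and methylation classes.

Repeat hits come from RepeatMasker-style tables (or a minimal TSV dialect)
and are filtered on hit length, library coverage and divergence; MITE
instances come from 12-column BLAST tables and must be perfect full-length
matches.  Location classes follow the convention that "included in" means
full containment while "overlapping" means >= 1 bp of shared sequence.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import GeneModel, IntronRecord

TE_LOCATION_CLASSES = (
    "intergenic", "intron", "exon", "exon-intron", "exon/intron", "other",
)

REPEAT_HIT_COLUMNS = [
    "chrom", "start", "end", "strand", "family",
    "library_length", "divergence", "is_te",
]

METHYLATION_CLASS_THRESHOLDS = {"CG": 0.9, "CHG": 0.2, "CHH": 0.1}


# ---------------------------------------------------------------------------
# Hit-table readers and filters
# ---------------------------------------------------------------------------

_NON_TE_KEYWORDS = ("Simple_repeat", "Low_complexity", "Satellite", "rRNA", "tRNA", "snRNA")


def read_repeatmasker_out(path: str | Path) -> pd.DataFrame:
    """Parse a RepeatMasker .out file into the internal repeat-hit table.

    Library length is reconstructed from the repeat-internal coordinates
    (end + remaining for plus hits, end + left-flank for minus hits);
    divergence is the percent-divergence column / 100.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        f = line.split()
        if len(f) < 15 or not f[0].replace(".", "").isdigit():
            continue  # header / blank lines
        chrom, qstart, qend = f[4], int(f[5]) - 1, int(f[6])
        strand = "+" if f[8] == "+" else "-"
        family = f[10]
        if strand == "+":
            rep_end, rep_left = int(f[12]), int(f[13].strip("()"))
        else:
            rep_end, rep_left = int(f[12]), int(f[11].strip("()"))
        library_length = rep_end + rep_left
        divergence = float(f[1]) / 100.0
        is_te = not any(k in family for k in _NON_TE_KEYWORDS)
        rows.append((chrom, qstart, qend, strand, family, library_length, divergence, is_te))
    return pd.DataFrame(rows, columns=REPEAT_HIT_COLUMNS)


def read_repeat_hits_tsv(path: str | Path) -> pd.DataFrame:
    """Minimal TSV dialect with a header naming the internal columns."""
    df = pd.read_csv(path, sep="\t")
    missing = set(REPEAT_HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"repeat hit table missing columns: {sorted(missing)}")
    return df[REPEAT_HIT_COLUMNS]


def filter_repeat_hits(
    hits: pd.DataFrame,
    min_length: int = 100,
    min_coverage: float = 0.70,
    max_divergence: float = 0.20,
) -> pd.DataFrame:
    """Keep TE-class hits >= min_length bp, covering >= min_coverage of the
    library consensus, with divergence <= max_divergence."""
    length = hits["end"] - hits["start"]
    coverage = length / hits["library_length"]
    keep = (
        hits["is_te"].astype(bool)
        & (length >= min_length)
        & (coverage >= min_coverage)
        & (hits["divergence"] <= max_divergence)
    )
    return hits.loc[keep].reset_index(drop=True)


BLAST12_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=BLAST12_COLUMNS)


def filter_mite_hits(
    blast_hits: pd.DataFrame,
    query_lengths: Mapping[str, int],
    max_evalue: float = 1e-40,
) -> pd.DataFrame:
    """Retain perfect, full-length MITE matches: e <= max_evalue, alignment
    length equal to the query length, zero mismatches and zero gaps."""
    qlen = blast_hits["qseqid"].map(query_lengths)
    if qlen.isna().any():
        missing = blast_hits.loc[qlen.isna(), "qseqid"].unique()
        raise ValueError(f"query length missing for: {sorted(missing)[:5]}")
    keep = (
        (blast_hits["evalue"] <= max_evalue)
        & (blast_hits["length"] == qlen)
        & (blast_hits["mismatch"] == 0)
        & (blast_hits["gapopen"] == 0)
    )
    return blast_hits.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# TE genomic-location taxonomy
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Sorted gene spans per chromosome for overlap queries."""

    def __init__(self, gene_models: Iterable[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for gene in gene_models:
            self.by_chrom.setdefault(gene.chrom, []).append(gene)
        for genes in self.by_chrom.values():
            genes.sort(key=lambda g: g.span[0])

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        return [
            g for g in self.by_chrom.get(chrom, [])
            if g.span[0] < end and g.span[1] > start
        ]


def classify_te_location(
    te: tuple[str, int, int],
    gene_models: Iterable[GeneModel] | _GeneIndex,
) -> str:
    """Assign one of the six location classes to a TE interval.

    intergenic: no gene-span overlap.  other: overlaps a gene span but is
    not fully inside any gene.  Within genes, the TE is "exon"/"intron"
    when fully contained in an exon/intron of every relevant transcript,
    "exon-intron" when it straddles an exon-intron boundary within one
    transcript, and "exon/intron" when fully exonic in one transcript but
    fully intronic in another.  exon-intron outranks exon/intron when a TE
    qualifies for both across different variants.
    """
    chrom, start, end = te
    index = gene_models if isinstance(gene_models, _GeneIndex) else _GeneIndex(gene_models)
    genes = index.overlapping(chrom, start, end)
    if not genes:
        return "intergenic"
    if not any(g.span[0] <= start and end <= g.span[1] for g in genes):
        return "other"
    verdicts: set[str] = set()
    for gene in genes:
        for tx in gene.transcripts:
            tstart, tend = tx.span
            if start >= tend or end <= tstart:
                continue
            in_exon = any(es <= start and end <= ee for es, ee in tx.exons)
            introns = [
                (tx.exons[i][1], tx.exons[i + 1][0])
                for i in range(len(tx.exons) - 1)
            ]
            in_intron = any(s <= start and end <= e for s, e in introns)
            if in_exon:
                verdicts.add("exon")
            elif in_intron:
                verdicts.add("intron")
            else:
                verdicts.add("exon-intron")
    if "exon-intron" in verdicts:
        return "exon-intron"
    if "exon" in verdicts and "intron" in verdicts:
        return "exon/intron"
    if verdicts == {"exon"}:
        return "exon"
    if verdicts == {"intron"}:
        return "intron"
    # inside a gene span but outside every transcript span
    return "other"


def classify_te_locations(
    tes: pd.DataFrame, gene_models: Iterable[GeneModel]
) -> pd.Series:
    index = _GeneIndex(gene_models)
    return pd.Series(
        [
            classify_te_location((r.chrom, r.start, r.end), index)
            for r in tes.itertuples(index=False)
        ],
        index=tes.index,
        name="location_class",
    )


def te_orientation_bias_test(n_sense: int, n_antisense: int) -> float:
    """Exact two-sided binomial test of sense/antisense symmetry (null 0.5)."""
    n = n_sense + n_antisense
    if n == 0:
        raise ValueError("orientation test undefined with zero TEs")
    return float(stats.binomtest(n_sense, n, 0.5, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# TE methylation classes
# ---------------------------------------------------------------------------

def classify_te_methylation(summary_row: Mapping[str, float]) -> dict[str, str]:
    """Per-context high/low/excluded class from a region methylation summary.

    Thresholds: mCG >= 0.9, mCHG >= 0.2, mCHH >= 0.1 are "high"; a context
    with fewer than 5 informative cytosines (NaN mean) is "excluded".
    """
    out = {}
    for context, threshold in METHYLATION_CLASS_THRESHOLDS.items():
        mean = summary_row.get(f"m{context}", np.nan)
        if mean is None or (isinstance(mean, float) and np.isnan(mean)):
            out[context] = "excluded"
        else:
            out[context] = "high" if mean >= threshold else "low"
    return out


# ---------------------------------------------------------------------------
# Intron overlap Venn
# ---------------------------------------------------------------------------

VENN_KEYS = (
    "het_only", "te_only", "repeat_only",
    "het_te", "het_repeat", "te_repeat", "het_te_repeat",
)


def venn_het_intron_te_repeat(introns: Iterable[IntronRecord]) -> dict[str, int]:
    """Counts of the seven overlap classes of the heterochromatic / TE /
    other-repeat flags over introns carrying at least one flag."""
    counts = dict.fromkeys(VENN_KEYS, 0)
    for i in introns:
        h, t, r = i.heterochromatic, i.contains_te, i.contains_repeat
        if not (h or t or r):
            continue
        if h and t and r:
            counts["het_te_repeat"] += 1
        elif h and t:
            counts["het_te"] += 1
        elif h and r:
            counts["het_repeat"] += 1
        elif t and r:
            counts["te_repeat"] += 1
        elif h:
            counts["het_only"] += 1
        elif t:
            counts["te_only"] += 1
        else:
            counts["repeat_only"] += 1
    return counts


def flag_intron_te_repeat_overlap(
    introns: list[IntronRecord], repeats: pd.DataFrame
) -> list[IntronRecord]:
    """Set contains_te / contains_repeat for repeats overlapping each intron.

    ``repeats`` needs chrom/start/end and a boolean is_te column; any
    overlap (>= 1 bp) counts.
    """
    by_chrom = {chrom: grp for chrom, grp in repeats.groupby("chrom")}
    for intron in introns:
        intron.contains_te = False
        intron.contains_repeat = False
        grp = by_chrom.get(intron.chrom)
        if grp is None:
            continue
        overlap = (grp["start"] < intron.end) & (grp["end"] > intron.start)
        if overlap.any():
            is_te = grp.loc[overlap, "is_te"].astype(bool)
            intron.contains_te = bool(is_te.any())
            intron.contains_repeat = bool((~is_te).any())
    return introns
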