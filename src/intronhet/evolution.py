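"""Ortholog screening and nucleotide substitution rates.

K_A and K_S follow the Nei-Gojobori (1986) method: synonymous and
nonsynonymous site counts by the fraction of synonymous single-nucleotide
changes per codon position (changes to stop codons excluded from the
denominator), observed differences by equal-weight averaging over all
minimal substitution pathways between codon pairs (pathways through stop
codons excluded, weights renormalized), and the Jukes-Cantor correction
d = -(3/4) ln(1 - (4/3) p).  Intron divergence K_I is the raw p-distance
over columns that are ungapped in both species and not repeat-masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import PermutationResult

NUCLEOTIDES = "ACGT"

_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def is_stop(codon: str) -> bool:
    return _build_codon_table()[codon] == "*"


class SaturationError(ValueError):
    """p-distance at or beyond 3/4: the Jukes-Cantor correction diverges."""


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes 1 site, split by the fraction of possible
    single-nucleotide changes (excluding changes to stops) that preserve
    the amino acid.
    """
    table = _build_codon_table()
    aa = table[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no site counts")
    syn_sites = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if table[alt] == "*":
                continue
            valid += 1
            if table[alt] == aa:
                syn += 1
        if valid:
            syn_sites += syn / valid
    return syn_sites, 3.0 - syn_sites


@lru_cache(maxsize=None)
def codon_pair_differences(codon1: str, codon2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons,
    averaged with equal weight over all minimal substitution pathways.

    Pathways passing through a stop codon are excluded and the weights
    renormalized; if every pathway is excluded, all are used.
    """
    table = _build_codon_table()
    diff_positions = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_positions:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff_positions):
        current = codon1
        syn = nonsyn = 0
        valid = True
        for step, pos in enumerate(order):
            nxt = current[:pos] + codon2[pos] + current[pos + 1:]
            if table[nxt] == "*" and step < len(order) - 1:
                valid = False
                break
            if table[nxt] == table[current]:
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if valid:
            pathways.append((syn, nonsyn))
    if not pathways:
        for order in permutations(diff_positions):
            current = codon1
            syn = nonsyn = 0
            for pos in order:
                nxt = current[:pos] + codon2[pos] + current[pos + 1:]
                if table[nxt] == table[current]:
                    syn += 1
                else:
                    nonsyn += 1
                current = nxt
            pathways.append((syn, nonsyn))
    syn_mean = sum(p[0] for p in pathways) / len(pathways)
    nonsyn_mean = sum(p[1] for p in pathways) / len(pathways)
    return syn_mean, nonsyn_mean


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4; distance undefined")
    if p == 0:
        return 0.0
    return -0.75 * np.log(1 - 4 * p / 3)


def nei_gojobori_rates(aligned_cds1: str, aligned_cds2: str) -> tuple[float, float]:
    """(K_A, K_S) between two aligned coding sequences.

    Codon columns containing a gap or ambiguity character in either row,
    or a stop codon, are skipped entirely.  Site counts are averaged
    between the two sequences; proportions are Jukes-Cantor corrected.
    """
    if len(aligned_cds1) != len(aligned_cds2):
        raise ValueError("aligned sequences differ in length")
    if len(aligned_cds1) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    table = _build_codon_table()
    s_sites = n_sites = 0.0
    s_diff = n_diff = 0.0
    n_codons = 0
    for i in range(0, len(aligned_cds1), 3):
        c1 = aligned_cds1[i:i + 3].upper()
        c2 = aligned_cds2[i:i + 3].upper()
        if any(b not in NUCLEOTIDES for b in c1 + c2):
            continue
        if table[c1] == "*" or table[c2] == "*":
            continue
        s1, n1 = codon_site_counts(c1)
        s2, n2 = codon_site_counts(c2)
        s_sites += (s1 + s2) / 2
        n_sites += (n1 + n2) / 2
        sd, nd = codon_pair_differences(c1, c2)
        s_diff += sd
        n_diff += nd
        n_codons += 1
    if n_codons == 0:
        raise ValueError("no comparable codons in the alignment")
    p_s = s_diff / s_sites if s_sites > 0 else 0.0
    p_n = n_diff / n_sites if n_sites > 0 else 0.0
    return jukes_cantor(p_n), jukes_cantor(p_s)


# ---------------------------------------------------------------------------
# Alignment containers and screening
# ---------------------------------------------------------------------------

@dataclass
class OrthologAlignmentPair:
    """Aligned ortholog pair: coding rows, intron rows with repeat masks,
    and per-column exon/intron annotation states per species."""

    gene_id: str
    cds1: str
    cds2: str
    introns: tuple[tuple[str, str, np.ndarray], ...] = ()
    states1: str = ""
    states2: str = ""


def structure_conservation(pair: OrthologAlignmentPair) -> float:
    """Fraction of aligned columns whose exon/intron annotation state
    matches between the two species."""
    if not pair.states1 or len(pair.states1) != len(pair.states2):
        raise ValueError(f"gene {pair.gene_id}: missing or unequal state strings")
    matches = sum(a == b for a, b in zip(pair.states1, pair.states2))
    return matches / len(pair.states1)


def screen_orthologs(
    hit_table: pd.DataFrame,
    alignments: Mapping[str, OrthologAlignmentPair],
    conservation_threshold: float = 0.8,
) -> list[OrthologAlignmentPair]:
    """Keep queries with exactly one candidate ortholog whose exon-intron
    structure is conserved over >= conservation_threshold of aligned
    columns.  ``hit_table`` needs columns query/candidate."""
    counts = hit_table.groupby("query")["candidate"].nunique()
    unique_queries = counts.index[counts == 1]
    retained = []
    for query in unique_queries:
        if query not in alignments:
            raise KeyError(f"alignment missing for retained query {query!r}")
        pair = alignments[query]
        if structure_conservation(pair) >= conservation_threshold:
            retained.append(pair)
    return retained


def intron_p_distance(
    intron1: str, intron2: str, repeat_mask: Sequence[bool]
) -> float:
    """p-distance over comparable columns: ungapped in both rows and not
    repeat-masked.  Raises if no column is comparable."""
    mask = np.asarray(repeat_mask, dtype=bool)
    if len(intron1) != len(intron2) or len(intron1) != mask.size:
        raise ValueError("intron rows and mask must share one length")
    a = np.frombuffer(intron1.upper().encode(), dtype="S1")
    b = np.frombuffer(intron2.upper().encode(), dtype="S1")
    bases = np.array([b"A", b"C", b"G", b"T"], dtype="S1")
    valid_bases = np.isin(a, bases) & np.isin(b, bases)
    comparable = valid_bases & ~mask
    n = int(comparable.sum())
    if n == 0:
        raise ValueError("no comparable columns (all gapped or masked)")
    return float((a[comparable] != b[comparable]).sum() / n)


# ---------------------------------------------------------------------------
# Per-gene tables, filtering and group summaries
# ---------------------------------------------------------------------------

def divergence_table(pairs: Iterable[OrthologAlignmentPair]) -> pd.DataFrame:
    """Per-gene K_A / K_S / K_A/K_S and the per-gene mean K_I."""
    rows = []
    for pair in pairs:
        ka, ks = nei_gojobori_rates(pair.cds1, pair.cds2)
        kis = [
            intron_p_distance(s1, s2, mask) for s1, s2, mask in pair.introns
        ]
        rows.append(
            {
                "gene_id": pair.gene_id,
                "K_A": ka,
                "K_S": ks,
                "ka_ks": ka / ks if ks > 0 else np.nan,
                "mean_K_I": float(np.mean(kis)) if kis else np.nan,
                "n_introns": len(kis),
            }
        )
    return pd.DataFrame(rows)


def ks_filter(divergences: pd.DataFrame, ks_max: float = 0.1) -> pd.DataFrame:
    """Discard genes with K_S strictly greater than ks_max."""
    return divergences.loc[divergences["K_S"] <= ks_max].reset_index(drop=True)


def group_rate_summary(
    divergences: pd.DataFrame,
    group_labels: Mapping[str, str] | pd.Series,
    mode: str = "ratio_of_means",
) -> pd.DataFrame:
    """Aggregate K_A/K_S (and mean K_I) per group.

    ``mode='ratio_of_means'`` (default) reports (mean K_A)/(mean K_S),
    which is stable when many K_S are near zero; ``mode='mean_of_ratios'``
    averages per-gene ratios over genes with K_S > 0.
    """
    if mode not in ("ratio_of_means", "mean_of_ratios"):
        raise ValueError("mode must be 'ratio_of_means' or 'mean_of_ratios'")
    df = divergences.copy()
    labels = pd.Series(group_labels) if isinstance(group_labels, Mapping) else group_labels
    df["group"] = df["gene_id"].map(labels)
    if df["group"].isna().any():
        missing = df.loc[df["group"].isna(), "gene_id"].tolist()
        raise ValueError(f"unlabeled genes: {missing[:5]}")
    rows = []
    for group, grp in df.groupby("group"):
        mean_ks = grp["K_S"].mean()
        if mode == "ratio_of_means":
            agg = grp["K_A"].mean() / mean_ks if mean_ks > 0 else np.nan
        else:
            ratios = grp.loc[grp["K_S"] > 0, "ka_ks"]
            agg = ratios.mean() if len(ratios) else np.nan
        rows.append(
            {
                "group": group,
                "n": len(grp),
                "ka_ks": agg,
                "mean_K_A": grp["K_A"].mean(),
                "mean_K_S": mean_ks,
                "mean_K_I": grp["mean_K_I"].mean(),
            }
        )
    return pd.DataFrame(rows)


def _kaks_aggregate_diff(a: np.ndarray, b: np.ndarray) -> float:
    """Difference of (mean K_A)/(mean K_S) between two (n, 2) groups."""
    return a[:, 0].mean() / a[:, 1].mean() - b[:, 0].mean() / b[:, 1].mean()


def group_permutation_test(
    values_a: Sequence[float] | np.ndarray,
    values_b: Sequence[float] | np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str | Callable[[np.ndarray, np.ndarray], float] = "mean_diff",
    alternative: str = "greater",
) -> PermutationResult:
    """Label-permutation test of a group difference.

    ``statistic`` is "mean_diff" (difference of group means over 1-D
    values), "kaks_diff" (difference of K_A/K_S ratio-of-means aggregates
    over (n, 2) arrays of per-gene (K_A, K_S)), or any callable.
    ``alternative`` fixes the tail a priori ("greater": group A larger;
    "less"; "two-sided"); p carries the add-one correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if statistic == "mean_diff":
        stat = lambda x, y: x.mean() - y.mean()  # noqa: E731
    elif statistic == "kaks_diff":
        stat = _kaks_aggregate_diff
    elif callable(statistic):
        stat = statistic
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = float(stat(a, b))
    pooled = np.concatenate([a, b], axis=0)
    n_a = a.shape[0]
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled.shape[0])
        na, nb = pooled[perm[:n_a]], pooled[perm[n_a:]]
        null_stat = stat(na, nb)
        if alternative == "greater":
            hits += null_stat >= observed
        elif alternative == "less":
            hits += null_stat <= observed
        else:
            hits += abs(null_stat) >= abs(observed)
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        p_value=(1 + hits) / (n_perm + 1),
        direction=alternative,
    )
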