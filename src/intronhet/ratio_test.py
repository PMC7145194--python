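"""Premature-termination detection from pre-/post-intron read counts.

For each intron, reads mapping upstream (pre) and downstream (post) are
compared between genotypes with a binomial-proportion logistic model:
post counts are the "successes" among pre + post reads, genotype is the
sole predictor, and the genotype term is assessed by a likelihood-ratio
test.  Because the genotype factor saturates the group proportions, the
LRT statistic has the closed form of a G-test on the aggregated 2x2
count table, which is what is computed here; replicates enter through
their summed counts, exactly as separate binomial observations would.
A single-replicate design falls back to an exact binomial test against
the control's observed proportion.  q-values are Benjamini-Hochberg
across all tested introns; q <= 0.01 flags a significant change in
downstream transcription.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .stats import fisher_enrichment

COUNT_COLUMNS = ["intron_id", "sample_id", "genotype", "pre_count", "post_count"]

RESULT_COLUMNS = [
    "intron_id", "coefficient", "p_value", "q_value",
    "significant", "direction", "separation_adjusted",
]

DEFAULT_Q_THRESHOLD = 0.01
DEFAULT_MIN_TOTAL = 10


def _binom_ll(successes: np.ndarray, totals: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood at the MLE proportion, per group."""
    with np.errstate(divide="ignore", invalid="ignore"):
        p = successes / totals
        ll = successes * np.log(p) + (totals - successes) * np.log(1 - p)
    return np.where((successes == 0) | (successes == totals), 0.0, ll)


def pre_post_ratio_glm_test(
    pairs: pd.DataFrame,
    control: str,
    treatment: str,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Genotype effect on the post/(pre+post) proportion, per intron.

    ``pairs`` has columns intron_id/sample_id/genotype/pre_count/post_count
    with >= 2 replicates per genotype.  Introns whose total (pre + post)
    count in either genotype is below ``min_total`` are skipped.  When an
    aggregate cell is zero (complete separation), 0.5 is added to all four
    cells and the intron is flagged in ``separation_adjusted``.  The
    coefficient is the log-odds difference treatment - control; direction
    "down" means reduced downstream transcription in the treatment.
    """
    df = pairs[pairs["genotype"].isin([control, treatment])]
    agg = (
        df.groupby(["intron_id", "genotype"])[["pre_count", "post_count"]]
        .sum()
        .unstack("genotype")
    )
    for g in (control, treatment):
        if ("pre_count", g) not in agg.columns:
            raise ValueError(f"genotype {g!r} absent from the count table")
    pre_c = agg[("pre_count", control)].to_numpy(dtype=float)
    post_c = agg[("post_count", control)].to_numpy(dtype=float)
    pre_t = agg[("pre_count", treatment)].to_numpy(dtype=float)
    post_t = agg[("post_count", treatment)].to_numpy(dtype=float)
    tested = ((pre_c + post_c) >= min_total) & ((pre_t + post_t) >= min_total)

    cells = np.stack([pre_c, post_c, pre_t, post_t], axis=1)
    separation = (cells == 0).any(axis=1)
    cells = np.where(separation[:, None], cells + 0.5, cells)
    pre_c, post_c, pre_t, post_t = cells.T

    tot_c, tot_t = pre_c + post_c, pre_t + post_t
    ll_full = _binom_ll(post_c, tot_c) + _binom_ll(post_t, tot_t)
    ll_null = _binom_ll(post_c + post_t, tot_c + tot_t)
    g_stat = np.maximum(2 * (ll_full - ll_null), 0.0)
    p = stats.chi2.sf(g_stat, df=1)
    coef = np.log(post_t / pre_t) - np.log(post_c / pre_c)

    out = pd.DataFrame(
        {
            "intron_id": agg.index,
            "coefficient": coef,
            "p_value": p,
            "separation_adjusted": separation,
        }
    )
    out = out.loc[tested].reset_index(drop=True)
    out["q_value"] = (
        multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        if len(out)
        else np.array([], dtype=float)
    )
    out["significant"] = out["q_value"] <= q_threshold
    out["direction"] = np.where(out["coefficient"] < 0, "down", "up")
    return out[RESULT_COLUMNS]


def pre_post_binomial_test(
    pairs: pd.DataFrame,
    control: str,
    treatment: str,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_total: int = DEFAULT_MIN_TOTAL,
) -> pd.DataFrame:
    """Single-replicate variant: exact two-sided binomial test of the
    treatment's post proportion against the control's observed proportion.

    Introns with zero control total (undefined null) or totals below
    ``min_total`` are skipped.
    """
    df = pairs[pairs["genotype"].isin([control, treatment])]
    agg = (
        df.groupby(["intron_id", "genotype"])[["pre_count", "post_count"]]
        .sum()
        .unstack("genotype")
    )
    rows = []
    for intron_id in agg.index:
        pre_c = int(agg.loc[intron_id, ("pre_count", control)])
        post_c = int(agg.loc[intron_id, ("post_count", control)])
        pre_t = int(agg.loc[intron_id, ("pre_count", treatment)])
        post_t = int(agg.loc[intron_id, ("post_count", treatment)])
        tot_c, tot_t = pre_c + post_c, pre_t + post_t
        if tot_c == 0 or tot_c < min_total or tot_t < min_total:
            continue
        p0 = post_c / tot_c
        if tot_t == 0:
            continue
        if p0 in (0.0, 1.0):
            # degenerate null: any deviation is impossible under it
            pval = 1.0 if (post_t / tot_t) == p0 else 0.0
        else:
            pval = stats.binomtest(post_t, tot_t, p0, alternative="two-sided").pvalue
        obs = post_t / tot_t
        coef = obs - p0
        rows.append((intron_id, coef, float(pval)))
    out = pd.DataFrame(rows, columns=["intron_id", "coefficient", "p_value"])
    out["q_value"] = (
        multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
        if len(out)
        else np.array([], dtype=float)
    )
    out["significant"] = out["q_value"] <= q_threshold
    out["direction"] = np.where(out["coefficient"] < 0, "down", "up")
    out["separation_adjusted"] = False
    return out[RESULT_COLUMNS]


def call_degs_and_intersect(
    result_sets: Mapping[str, pd.DataFrame],
    intron_to_gene: Mapping[str, str],
    het_gene_ids: set[str],
    universe_gene_ids: set[str],
) -> dict:
    """Roll per-intron calls up to genes, intersect DEG sets across
    comparisons, and test heterochromatic-intron enrichment.

    A gene is a DEG in a comparison iff any of its introns is significant.
    Returns per-comparison DEG sets, their intersection, pairwise Fisher
    overlap p-values, and the Fisher enrichment of heterochromatic genes
    among intersected DEGs against the gene universe.
    """
    if len(result_sets) < 2:
        raise ValueError("need at least two comparisons to intersect")
    if not universe_gene_ids:
        raise ValueError("empty gene universe")
    deg_sets: dict[str, set[str]] = {}
    for name, res in result_sets.items():
        sig = res.loc[res["significant"], "intron_id"]
        deg_sets[name] = {intron_to_gene[i] for i in sig if i in intron_to_gene}
    names = list(deg_sets)
    intersection = set.intersection(*deg_sets.values())

    overlap_p: dict[tuple[str, str], float] = {}
    n_u = len(universe_gene_ids)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            s1, s2 = deg_sets[names[i]], deg_sets[names[j]]
            a = len(s1 & s2)
            b = len(s1 - s2)
            c = len(s2 - s1)
            d = n_u - a - b - c
            overlap_p[(names[i], names[j])] = fisher_enrichment(a, b, c, d)[1]

    het_in_universe = het_gene_ids & universe_gene_ids
    a = len(intersection & het_in_universe)
    b = len(intersection - het_in_universe)
    c = len(het_in_universe - intersection)
    d = n_u - a - b - c
    het_odds, het_p = fisher_enrichment(a, b, c, d)
    return {
        "deg_sets": deg_sets,
        "intersection": intersection,
        "pairwise_overlap_p": overlap_p,
        "het_enrichment_odds_ratio": het_odds,
        "het_enrichment_p": het_p,
    }


def relative_five_three_ratio(
    mutant_pair: tuple[float, float], wildtype_pair: tuple[float, float]
) -> float:
    """(pre/post in mutant) / (pre/post in wild type); 1.0 means no change,
    > 1 means relatively depleted downstream transcription in the mutant."""
    pre_m, post_m = mutant_pair
    pre_w, post_w = wildtype_pair
    if min(pre_m, post_m, pre_w, post_w) <= 0:
        raise ValueError("all four counts must be positive")
    return (pre_m / post_m) / (pre_w / post_w)
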