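"""Enrichment and expression statistics.

Covers the positional permutation test for 5'-bias of heterochromatic
introns, Fisher's exact enrichment, a ROKU-style tissue-specificity
entropy (Shannon entropy of absolute deviations from a one-step Tukey
biweight), the rank-sum effect size r = |Z|/sqrt(N), and TPM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PermutationResult:
    observed: float
    n_perm: int
    p_value: float
    direction: str

    def __post_init__(self) -> None:
        assert 0 < self.p_value <= 1


def positional_permutation_test(
    het_ordinals: Sequence[int],
    all_ordinals: Sequence[int],
    n_perm: int = 100_000,
    seed: int = 0,
    alternative: str = "less",
) -> PermutationResult:
    """Is the mean ordinal of the heterochromatic introns smaller than
    expected for a random same-sized subset of all introns?

    The null resamples size-matched subsets without replacement from the
    full ordinal multiset; p carries the add-one correction
    (1 + #{null <= obs}) / (n_perm + 1) for the default lower tail.
    """
    het = np.asarray(het_ordinals, dtype=float)
    full = np.asarray(all_ordinals, dtype=float)
    if het.size > full.size:
        raise ValueError("heterochromatic set larger than the full intron set")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("less", "greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    rng = np.random.default_rng(seed)
    observed = float(het.mean())
    k = het.size
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = full[rng.choice(full.size, size=k, replace=False)].mean()
    if alternative == "less":
        hits = int((null <= observed).sum())
    elif alternative == "greater":
        hits = int((null >= observed).sum())
    else:
        center = full.mean()
        hits = int((np.abs(null - center) >= abs(observed - center)).sum())
    return PermutationResult(
        observed=observed,
        n_perm=n_perm,
        p_value=(1 + hits) / (n_perm + 1),
        direction=alternative,
    )


def fisher_enrichment(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (sample odds ratio a*d/(b*c), p).  Degenerate tables (a zero
    margin) give p = 1 and odds ratio NaN.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return float("nan"), 1.0
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return odds, p


def tukey_biweight(x: np.ndarray, c: float = 5.0, epsilon: float = 1e-4) -> float:
    """One-step Tukey biweight location estimate (ROKU's robust center)."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    u = (x - med) / (c * mad + epsilon)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    if w.sum() == 0:
        return float(med)
    return float(np.sum(w * x) / np.sum(w))


def roku_entropy(
    expression: Sequence[float], c: float = 5.0, epsilon: float = 1e-4
) -> float:
    """Modified Shannon entropy H' of an expression vector, in bits.

    Deviations from the one-step Tukey biweight are normalized into a
    probability vector whose entropy is returned; a constant vector (zero
    total deviation) maps to the maximum log2(n).  Low H' means the gene's
    expression is concentrated in few conditions (tissue-specific).
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("expression vector must be 1-D with length >= 2")
    if not np.all(np.isfinite(x)) or (x < 0).any():
        raise ValueError("expression values must be finite and non-negative")
    w = tukey_biweight(x, c=c, epsilon=epsilon)
    dev = np.abs(x - w)
    total = dev.sum()
    if total == 0:
        return float(np.log2(x.size))
    p = dev / total
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def wilcoxon_effect_size(
    group_a: Sequence[float], group_b: Sequence[float]
) -> float:
    """Rank-sum effect size r = |Z| / sqrt(n_a + n_b) with tie correction.

    Z is the normal approximation of the Mann-Whitney U statistic; fully
    tied data give r = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0
    z = (u - mu) / np.sqrt(var)
    return float(abs(z) / np.sqrt(n))


def compute_tpm(
    counts: Sequence[float] | pd.Series,
    effective_lengths: Sequence[float] | pd.Series,
) -> np.ndarray | pd.Series:
    """Transcripts per million: rate = count/length, scaled to sum 1e6."""
    counts_arr = np.asarray(counts, dtype=float)
    lengths_arr = np.asarray(effective_lengths, dtype=float)
    if (lengths_arr <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts_arr / lengths_arr
    total = rate.sum()
    tpm = np.zeros_like(rate) if total == 0 else rate / total * 1e6
    if isinstance(counts, pd.Series):
        return pd.Series(tpm, index=counts.index, name="tpm")
    return tpm


def specificity_table(
    expression: pd.DataFrame, c: float = 5.0, epsilon: float = 1e-4
) -> pd.DataFrame:
    """Per-gene ROKU entropy over a genes x conditions matrix."""
    h = expression.apply(
        lambda row: roku_entropy(row.to_numpy(), c=c, epsilon=epsilon), axis=1
    )
    return pd.DataFrame({"gene_id": expression.index, "entropy": h.to_numpy()})
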