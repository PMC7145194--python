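"""Methylcytosine calling from per-cytosine bisulfite counts.

The workflow mirrors standard plant WGBS practice: estimate the bisulfite
conversion rate from a known-unmethylated control contig (the chloroplast),
discard sites with extreme coverage, test each remaining cytosine for
methylation with a one-tailed binomial test against the non-conversion
error rate, and control the FDR per sequence context with
Benjamini-Hochberg.  Methylation level is always #C/(#C + #T).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CONTEXTS

DEFAULT_MIN_COVERAGE = 3
DEFAULT_MAX_COVERAGE = 100
DEFAULT_FDR = 0.05
MIN_REGION_SITES = 5


class ConversionEstimationError(ValueError):
    pass


def estimate_conversion_rate(control_sites: pd.DataFrame) -> float:
    """Conversion rate = converted (unmethylated) reads / total reads over
    an unmethylated control."""
    total = int(control_sites["n_meth"].sum() + control_sites["n_unmeth"].sum())
    if total == 0:
        raise ConversionEstimationError("control sites have zero total coverage")
    return float(control_sites["n_unmeth"].sum()) / total


def filter_coverage(
    sites: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    max_coverage: int = DEFAULT_MAX_COVERAGE,
) -> pd.DataFrame:
    """Keep sites with min_coverage <= coverage <= max_coverage (inclusive)."""
    cov = sites["n_meth"] + sites["n_unmeth"]
    return sites.loc[(cov >= min_coverage) & (cov <= max_coverage)].reset_index(drop=True)


def methylation_level(n_meth: int, n_unmeth: int) -> float:
    cov = n_meth + n_unmeth
    if cov == 0:
        raise ValueError("methylation level undefined at zero coverage")
    return n_meth / cov


def call_methylcytosines(
    sites: pd.DataFrame,
    conversion_rate: float,
    fdr_threshold: float = DEFAULT_FDR,
) -> pd.DataFrame:
    """Per-site binomial test against the bisulfite non-conversion rate.

    p is the upper-tail probability of observing >= n_meth methylated reads
    out of coverage under error rate (1 - conversion_rate).  q-values are
    Benjamini-Hochberg within each context; a site is a methylcytosine iff
    q <= fdr_threshold.
    """
    if not 0 < conversion_rate <= 1:
        raise ValueError("conversion_rate must be in (0, 1]")
    out = sites.copy()
    n = (out["n_meth"] + out["n_unmeth"]).to_numpy()
    k = out["n_meth"].to_numpy()
    if (n == 0).any():
        raise ValueError("call_methylcytosines requires coverage-filtered input")
    error_rate = 1.0 - conversion_rate
    # sf(k-1) = P(X >= k); exact even for error_rate == 0 (p=0 unless k==0)
    out["level"] = k / n
    out["p_value"] = stats.binom.sf(k - 1, n, error_rate)
    out["q_value"] = np.nan
    for context in CONTEXTS:
        mask = (out["context"] == context).to_numpy()
        if mask.any():
            out.loc[mask, "q_value"] = multipletests(
                out.loc[mask, "p_value"].to_numpy(), method="fdr_bh"
            )[1]
    out["is_methylcytosine"] = out["q_value"] <= fdr_threshold
    return out


def summarize_region_methylation(
    regions: pd.DataFrame,
    calls: pd.DataFrame,
    min_sites: int = MIN_REGION_SITES,
) -> pd.DataFrame:
    """Per-region, per-context mean methylation level over covered sites.

    ``regions`` needs columns chrom/start/end/name; ``calls`` is the output
    of :func:`call_methylcytosines` (only ``level`` is used, i.e. all
    coverage-passing sites contribute, called or not).  A context mean is
    reported as NaN when fewer than ``min_sites`` informative sites fall in
    the region; both strands are pooled.
    """
    records = []
    calls_by_chrom = {
        chrom: grp.sort_values("pos") for chrom, grp in calls.groupby("chrom")
    }
    for row in regions.itertuples(index=False):
        rec: dict = {"name": row.name}
        grp = calls_by_chrom.get(row.chrom)
        for context in CONTEXTS:
            mean, count = np.nan, 0
            if grp is not None:
                pos = grp["pos"].to_numpy()
                lo = np.searchsorted(pos, row.start, side="left")
                hi = np.searchsorted(pos, row.end, side="left")
                sub = grp.iloc[lo:hi]
                sub = sub[sub["context"] == context]
                count = len(sub)
                if count >= min_sites:
                    mean = float(sub["level"].mean())
            rec[f"m{context}"] = mean
            rec[f"n_{context}"] = count
        records.append(rec)
    return pd.DataFrame.from_records(records)
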