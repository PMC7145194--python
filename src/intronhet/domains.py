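"""Heterochromatic-domain calling from CHG methylcytosine calls.

A heterochromatic domain is a maximal run of >= 5 consecutively called
CHG methylcytosines whose unweighted mean methylation level is >= 0.5.
"Consecutive" is read over CHG sites in genomic order with both strands
pooled: a covered CHG site that failed the methylcytosine call breaks a
run, while intervening CG/CHH cytosines are invisible to the rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import IntronRecord

MIN_DOMAIN_SITES = 5
MIN_DOMAIN_MEAN = 0.5

DOMAIN_COLUMNS = ["chrom", "start", "end", "n_sites", "mean_mchg"]


def find_heterochromatic_domains(
    chg_calls: pd.DataFrame,
    min_sites: int = MIN_DOMAIN_SITES,
    min_mean: float = MIN_DOMAIN_MEAN,
) -> pd.DataFrame:
    """Call domains from CHG-context methylation calls sorted by (chrom, pos).

    The domain interval spans the first through last member site
    (half-open: last position + 1).  A maximal called run whose mean level
    falls below ``min_mean`` yields no domain; no sub-run search is done.
    """
    if not (chg_calls["context"] == "CHG").all():
        raise ValueError("find_heterochromatic_domains expects CHG-context calls only")
    for _, grp in chg_calls.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError("calls must be sorted by (chrom, pos)")

    rows = []
    for chrom, grp in chg_calls.groupby("chrom", sort=False):
        called = grp["is_methylcytosine"].to_numpy(dtype=bool)
        pos = grp["pos"].to_numpy()
        level = grp["level"].to_numpy(dtype=float)
        if called.size == 0:
            continue
        # maximal runs of True
        padded = np.concatenate([[False], called, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive indices
        for i, j in zip(starts, ends):
            n = j - i
            if n < min_sites:
                continue
            mean = level[i:j].mean()
            if mean >= min_mean:
                rows.append((chrom, int(pos[i]), int(pos[j - 1]) + 1, int(n), float(mean)))
    return pd.DataFrame(rows, columns=DOMAIN_COLUMNS)


def domains_to_bed(domains: pd.DataFrame) -> pd.DataFrame:
    """BED6 with score = mean mCHG scaled to 0-1000."""
    bed = pd.DataFrame(
        {
            "chrom": domains["chrom"],
            "start": domains["start"],
            "end": domains["end"],
            "name": [
                f"het_domain_{i}:{n}" for i, n in enumerate(domains["n_sites"])
            ],
            "score": (domains["mean_mchg"] * 1000).round().astype(int),
            "strand": ".",
        }
    )
    return bed


def classify_heterochromatic_introns(
    introns: list[IntronRecord],
    domains: pd.DataFrame,
    mode: str = "contained",
) -> list[IntronRecord]:
    """Flag introns that contain a heterochromatic domain.

    ``mode='contained'`` (default) requires the domain to lie fully inside
    the intron interval; ``mode='overlap'`` accepts any overlap.  The flags
    are set in place on the supplied records, which are also returned.
    """
    if mode not in ("contained", "overlap"):
        raise ValueError("mode must be 'contained' or 'overlap'")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in domains.groupby("chrom"):
        grp = grp.sort_values("start")
        by_chrom[chrom] = (grp["start"].to_numpy(), grp["end"].to_numpy())
    for intron in introns:
        intron.heterochromatic = False
        arrs = by_chrom.get(intron.chrom)
        if arrs is None:
            continue
        starts, ends = arrs
        if mode == "contained":
            lo = np.searchsorted(starts, intron.start, side="left")
            hi = np.searchsorted(starts, intron.end, side="left")
            intron.heterochromatic = bool((ends[lo:hi] <= intron.end).any())
        else:
            overlap = (starts < intron.end) & (ends > intron.start)
            intron.heterochromatic = bool(overlap.any())
    return introns


def heterochromatic_gene_ids(introns: list[IntronRecord]) -> set[str]:
    """Genes with >= 1 heterochromatic intron in any transcript."""
    return {i.gene_id for i in introns if i.heterochromatic}


@dataclass(frozen=True)
class IntronPositionDistribution:
    fractions: np.ndarray  # index 0 = ordinal 1; last bin pools >= max_bin
    mean_ordinal: float
    n: int


def intron_position_distribution(
    introns: list[IntronRecord] | list[int],
    max_bin: int = 10,
) -> IntronPositionDistribution:
    """Distribution of intron ordinals with the tail pooled at ``max_bin``.

    The mean is computed on raw (unpooled) ordinals.
    """
    ordinals = np.asarray(
        [i.ordinal if isinstance(i, IntronRecord) else int(i) for i in introns]
    )
    if ordinals.size == 0:
        raise ValueError("cannot summarize an empty intron set")
    clipped = np.minimum(ordinals, max_bin)
    counts = np.bincount(clipped, minlength=max_bin + 1)[1:]
    return IntronPositionDistribution(
        fractions=counts / ordinals.size,
        mean_ordinal=float(ordinals.mean()),
        n=int(ordinals.size),
    )
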