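import numpy as np
import pandas as pd
import pytest

from intronhet.core_io import GeneModel, TranscriptModel


@pytest.fixture
def three_exon_gene_plus():
    tx = TranscriptModel("tA.t1", ((0, 100), (200, 300), (400, 500)))
    return GeneModel("tA", "chr1", "+", (tx,))


@pytest.fixture
def three_exon_gene_minus():
    tx = TranscriptModel("tB.t1", ((0, 100), (200, 300), (400, 500)))
    return GeneModel("tB", "chr1", "-", (tx,))


def random_chg_calls(rng: np.random.Generator, n: int, chrom: str = "chr1") -> pd.DataFrame:
    """Random CHG methylation-call table for domain-caller tests."""
    pos = np.sort(rng.choice(np.arange(10 * n), size=n, replace=False))
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "strand": np.where(rng.random(n) < 0.5, "+", "-"),
            "context": "CHG",
            "level": rng.random(n).round(3),
            "is_methylcytosine": rng.random(n) < 0.55,
        }
    )


def brute_force_domains(calls: pd.DataFrame, min_sites: int = 5, min_mean: float = 0.5):
    """Independent run-enumeration oracle for the domain caller: walk the
    sites, collect maximal called runs, apply both thresholds."""
    out = []
    for chrom, grp in calls.groupby("chrom", sort=False):
        run = []
        rows = list(grp.itertuples(index=False)) + [None]
        for row in rows:
            if row is not None and row.is_methylcytosine:
                run.append(row)
                continue
            if len(run) >= min_sites:
                mean = sum(r.level for r in run) / len(run)
                if mean >= min_mean:
                    out.append(
                        (chrom, run[0].pos, run[-1].pos + 1, len(run), mean)
                    )
            run = []
    return out
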