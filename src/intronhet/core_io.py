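"""Gene-model containers, intron derivation, genomic binning and flat-file I/O.

Internal coordinates are uniformly 0-based half-open.  On disk, GFF3 is
1-based closed and BED is 0-based half-open; the conversion happens only in
the readers/writers here.  The per-cytosine report dialect is six
tab-separated columns (chrom, 1-based position, strand, context,
methylated count, unmethylated count) with an optional, auto-detected
header line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CHG", "CHH")

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "context", "n_meth", "n_unmeth"]

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class MalformedAnnotationError(ValueError):
    """Raised when a gene model violates its structural invariants."""


class CoordinateError(ValueError):
    """Raised when a feature lies outside its chromosome."""


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered list of exon intervals (0-based half-open)."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(tuple(e) for e in self.exons))

    def validate(self) -> None:
        if not self.exons:
            raise MalformedAnnotationError(
                f"transcript {self.transcript_id} has no exons"
            )
        prev_end = -1
        for start, end in self.exons:
            if end <= start:
                raise MalformedAnnotationError(
                    f"transcript {self.transcript_id} has empty exon [{start},{end})"
                )
            if start < prev_end:
                raise MalformedAnnotationError(
                    f"transcript {self.transcript_id} has overlapping or unsorted exons"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if self.strand not in ("+", "-"):
            raise MalformedAnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    def validate(self) -> None:
        if not self.transcripts:
            raise MalformedAnnotationError(f"gene {self.gene_id} has no transcripts")
        for tx in self.transcripts:
            tx.validate()

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(tx.span for tx in self.transcripts))
        return min(starts), max(ends)


@dataclass
class IntronRecord:
    """One inter-exon gap of one transcript, with its 5'-based ordinal.

    Ordinal 1 is the most promoter-proximal intron in transcript
    orientation, so on the minus strand ordinals run against genomic
    coordinates.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ordinal: int
    heterochromatic: bool = False
    contains_te: bool = False
    contains_repeat: bool = False

    @property
    def intron_id(self) -> str:
        return f"{self.gene_id}:{self.transcript_id}:{self.ordinal}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CytosineRecord:
    chrom: str
    pos: int
    strand: str
    context: str
    n_meth: int
    n_unmeth: int

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown cytosine context {self.context!r}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


def derive_introns(gene_models: Iterable[GeneModel]) -> list[IntronRecord]:
    """Enumerate introns per transcript with 5'-based ordinals.

    Identical genomic intervals shared by several transcripts yield one
    record per transcript, matching per-splice-variant counting.
    """
    introns: list[IntronRecord] = []
    for gene in gene_models:
        gene.validate()
        for tx in gene.transcripts:
            gaps = [
                (tx.exons[i][1], tx.exons[i + 1][0])
                for i in range(len(tx.exons) - 1)
            ]
            if any(end <= start for start, end in gaps):
                raise MalformedAnnotationError(
                    f"transcript {tx.transcript_id} has touching or overlapping exons"
                )
            if gene.strand == "-":
                ordered = list(reversed(gaps))
            else:
                ordered = gaps
            for ordinal, (start, end) in enumerate(ordered, start=1):
                introns.append(
                    IntronRecord(
                        gene_id=gene.gene_id,
                        transcript_id=tx.transcript_id,
                        chrom=gene.chrom,
                        strand=gene.strand,
                        start=start,
                        end=end,
                        ordinal=ordinal,
                    )
                )
    return introns


def density_in_bins(
    features: Sequence[tuple[str, int, int]],
    chrom_lengths: Mapping[str, int],
    bin_size: int,
) -> dict[str, np.ndarray]:
    """Count features per fixed-width bin; each feature is assigned to the
    bin containing its start coordinate."""
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    counts = {
        chrom: np.zeros(max(1, -(-length // bin_size)), dtype=int)
        for chrom, length in chrom_lengths.items()
    }
    for chrom, start, _end in features:
        if chrom not in counts:
            raise CoordinateError(f"feature on unknown chromosome {chrom!r}")
        if start < 0 or start >= chrom_lengths[chrom]:
            raise CoordinateError(
                f"feature start {start} outside chromosome {chrom} "
                f"(length {chrom_lengths[chrom]})"
            )
        counts[chrom][start // bin_size] += 1
    return counts


# ---------------------------------------------------------------------------
# GFF3 (gene / mRNA / exon subset)
# ---------------------------------------------------------------------------

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gene in genes:
        gstart, gend = gene.span
        lines.append(
            "\t".join(
                [
                    gene.chrom, "intronhet", "gene",
                    str(gstart + 1), str(gend), ".", gene.strand, ".",
                    f"ID={gene.gene_id}",
                ]
            )
        )
        for tx in gene.transcripts:
            tstart, tend = tx.span
            lines.append(
                "\t".join(
                    [
                        gene.chrom, "intronhet", "mRNA",
                        str(tstart + 1), str(tend), ".", gene.strand, ".",
                        f"ID={tx.transcript_id};Parent={gene.gene_id}",
                    ]
                )
            )
            for i, (start, end) in enumerate(tx.exons, start=1):
                lines.append(
                    "\t".join(
                        [
                            gene.chrom, "intronhet", "exon",
                            str(start + 1), str(end), ".", gene.strand, ".",
                            f"ID={tx.transcript_id}.exon{i};Parent={tx.transcript_id}",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _gff3_attributes(field9: str) -> dict[str, str]:
    out = {}
    for item in field9.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key] = value
    return out


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Read a gene/mRNA/exon GFF3 into GeneModel objects (0-based internal)."""
    genes: dict[str, dict] = {}
    tx_parent: dict[str, str] = {}
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_order: list[str] = []
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        f = raw.split("\t")
        if len(f) != 9:
            raise MalformedAnnotationError(f"bad GFF3 line: {raw!r}")
        chrom, _src, ftype, start1, end1, _score, strand, _phase, attrs = f
        a = _gff3_attributes(attrs)
        if ftype == "gene":
            genes[a["ID"]] = {"chrom": chrom, "strand": strand}
        elif ftype in ("mRNA", "transcript"):
            tx_parent[a["ID"]] = a["Parent"]
            tx_exons.setdefault(a["ID"], [])
            tx_order.append(a["ID"])
        elif ftype == "exon":
            parent = a["Parent"]
            tx_exons.setdefault(parent, []).append((int(start1) - 1, int(end1)))
    out: list[GeneModel] = []
    gene_tx: dict[str, list[TranscriptModel]] = {g: [] for g in genes}
    for tx_id in tx_order:
        exons = sorted(tx_exons.get(tx_id, []))
        gene_tx[tx_parent[tx_id]].append(TranscriptModel(tx_id, tuple(exons)))
    for gene_id, info in genes.items():
        gene = GeneModel(gene_id, info["chrom"], info["strand"], tuple(gene_tx[gene_id]))
        gene.validate()
        out.append(gene)
    return out


# ---------------------------------------------------------------------------
# BED6
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     dtype={0: str})
    df.columns = BED_COLUMNS[: df.shape[1]]
    return df


def introns_to_bed(introns: Iterable[IntronRecord]) -> pd.DataFrame:
    """BED6 table of introns; name encodes gene:transcript:ordinal."""
    rows = [
        (i.chrom, i.start, i.end, i.intron_id, 0, i.strand) for i in introns
    ]
    return pd.DataFrame(rows, columns=BED_COLUMNS)


# ---------------------------------------------------------------------------
# Cytosine report
# ---------------------------------------------------------------------------

def write_cytosine_report(df: pd.DataFrame, path: str | Path, header: bool = True) -> None:
    out = df[CYTOSINE_COLUMNS].copy()
    out["pos"] = out["pos"].astype(int) + 1  # 1-based on disk
    out.to_csv(path, sep="\t", index=False, header=header)


def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read the six-column cytosine report; a header line is auto-detected."""
    with open(path) as fh:
        first = fh.readline()
    fields = first.rstrip("\n").split("\t")
    has_header = len(fields) >= 2 and not fields[1].isdigit()
    df = pd.read_csv(
        path, sep="\t",
        header=0 if has_header else None,
        names=CYTOSINE_COLUMNS,
        dtype={"chrom": str, "strand": str, "context": str},
    )
    df["pos"] = df["pos"].astype(int) - 1
    bad = ~df["context"].isin(CONTEXTS)
    if bad.any():
        raise ValueError(
            f"unknown cytosine context(s): {sorted(df.loc[bad, 'context'].unique())}"
        )
    return df


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
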