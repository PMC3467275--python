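"""Plain-text genomics I/O: BED reads, UCSC refGene annotation, bedGraph
tracks, BED5 region lists and TSV matrices.

All coordinates are 0-based half-open throughout the package (the native
convention of both BED and refGene.txt).  Readers validate and reject
malformed rows rather than silently coercing them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: maximum -log10(p) score written to BED5 region files
MAX_BED_SCORE = 300.0


@dataclass(frozen=True)
class MappedRead:
    """A uniquely mapped sequencing read: ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid read interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class GeneRecord:
    """A transcript with strand-aware TSS/TES.

    ``tx_start``/``tx_end`` are 0-based half-open.  For a minus-strand
    transcript the TSS is the half-open end coordinate (UCSC convention);
    the TES is the opposite end.  Splice variants and alternative TSS are
    kept as separate records.
    """

    transcript_id: str
    gene_symbol: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValueError(
                f"{self.transcript_id}: tx_start {self.tx_start} >= tx_end {self.tx_end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end

    @property
    def tes(self) -> int:
        return self.tx_end if self.strand == "+" else self.tx_start


def read_bed_reads(
    path: str | Path, chrom_sizes: Mapping[str, int] | None = None
) -> list[MappedRead]:
    """Read mapped reads from a >=6 column BED file.

    Rows on chromosomes absent from ``chrom_sizes`` (when given) are dropped
    with a single logged warning reporting the count.  Malformed rows raise
    ``ValueError`` naming the offending line number (1-based).
    """
    reads: list[MappedRead] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >=6 BED columns")
            chrom, start_s, end_s, _name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if chrom_sizes is not None and chrom not in chrom_sizes:
                dropped += 1
                continue
            try:
                reads.append(MappedRead(chrom, start, end, strand))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    if dropped:
        logger.warning(
            "%s: dropped %d reads on chromosomes absent from the genome", path, dropped
        )
    return reads


def read_refgene(path: str | Path) -> list[GeneRecord]:
    """Parse a UCSC ``refGene.txt`` dialect annotation.

    Expected tab-separated columns: (bin, name, chrom, strand, txStart,
    txEnd, ...); column 13 (``name2``), when present, provides the gene
    symbol.  One record per row — splice variants and alternative TSS stay
    separate.
    """
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >=6 refGene columns")
            name, chrom, strand = fields[1], fields[2], fields[3]
            if strand not in STRANDS:
                raise ValueError(f"{path}: line {lineno}: unknown strand {strand!r}")
            try:
                tx_start, tx_end = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer txStart/txEnd") from exc
            symbol = fields[12] if len(fields) > 12 and fields[12] else name
            try:
                genes.append(GeneRecord(name, symbol, chrom, strand, tx_start, tx_end))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chromosome sizes file."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected name<TAB>length")
            length = int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}: line {lineno}: non-positive length")
            sizes[fields[0]] = length
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


def write_bedgraph(track, path: str | Path) -> None:
    """Write a :class:`~epimark.coverage.BinnedTrack` as bedGraph.

    Zero-valued bins are omitted; an all-zero track yields a header-only
    file.  Non-zero bin values round-trip exactly through
    :func:`read_bedgraph`.
    """
    with open(path, "w") as fh:
        fh.write("track type=bedGraph\n")
        bs = track.bin_size
        for chrom in track.counts:
            values = track.counts[chrom]
            for i in values.nonzero()[0]:
                v = values[i]
                v_repr = repr(int(v)) if float(v).is_integer() else repr(float(v))
                fh.write(f"{chrom}\t{i * bs}\t{(i + 1) * bs}\t{v_repr}\n")


def read_bedgraph(path: str | Path, chrom_sizes: Mapping[str, int], bin_size: int = 100):
    """Read a bedGraph of contiguous ``bin_size`` bins back into a track.

    The returned track carries ``total_mapped_reads`` equal to the rounded
    sum of values (exact for raw-count tracks).
    """
    import numpy as np

    from .coverage import BinnedTrack

    counts = {
        chrom: np.zeros(-(-length // bin_size), dtype=float)
        for chrom, length in chrom_sizes.items()
    }
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start_s, end_s, value_s = line.split("\t")[:4]
            start, end = int(start_s), int(end_s)
            if end - start != bin_size or start % bin_size:
                raise ValueError(
                    f"{path}: line {lineno}: interval is not an aligned {bin_size}-bp bin"
                )
            counts[chrom][start // bin_size] = float(value_s)
    total = int(round(sum(float(c.sum()) for c in counts.values())))
    return BinnedTrack(counts=counts, bin_size=bin_size, total_mapped_reads=total)


def region_score(p_value: float) -> float:
    """-log10(p) capped at 300 (p=0 maps to the cap)."""
    if p_value <= 0.0:
        return MAX_BED_SCORE
    return min(-math.log10(p_value), MAX_BED_SCORE)


def write_regions_bed(regions: Iterable, path: str | Path) -> None:
    """Write enriched regions as BED5 with score = -log10(min_p), capped."""
    with open(path, "w") as fh:
        for i, region in enumerate(regions, start=1):
            score = region_score(region.min_p)
            fh.write(
                f"{region.chrom}\t{region.start}\t{region.end}\t"
                f"region_{i}\t{score:g}\n"
            )


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path, index_label: str = "gene") -> None:
    """Write an occupancy matrix as TSV, rows in annotation order."""
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def genes_to_dataframe(genes: Sequence[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [g.transcript_id for g in genes],
            "gene_symbol": [g.gene_symbol for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tx_start": [g.tx_start for g in genes],
            "tx_end": [g.tx_end for g in genes],
        }
    )
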