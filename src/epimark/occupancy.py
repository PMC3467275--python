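"""Normalized interval occupancy over gene-anchored intervals.

Occupancy of an interval is

    reads_in_interval * 5,000,000 / (total_mapped_reads * length_in_kb)

i.e. fragment midpoints per kb per 5 million mapped reads.  Intervals are
anchored on the transcript: the TSS window (TSS +/- 2.5 kb), the promoter
(the 2.5 kb strand-aware upstream of the TSS) and the gene body (TSS to
TES).  The occupancy matrix holds one row per transcript and one column
per (mark, stage) pair.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .coverage import NORMALIZATION_SCALE, MidpointSample
from .io_formats import GeneRecord

MARKS = ("H3K4me2", "H3K27me3")
STAGES = ("E17.5", "PN1", "PN7", "PN15")
GENOTYPES = ("wt", "rd1")

INTERVAL_KINDS = ("tss", "promoter", "body")

DEFAULT_TSS_FLANK = 2500


def matrix_columns(marks: Sequence[str] = MARKS, stages: Sequence[str] = STAGES) -> list[str]:
    """Canonical column order: mark-major, stage-minor."""
    return [f"{mark}_{stage}" for mark in marks for stage in stages]


def gene_interval(
    gene: GeneRecord,
    kind: str,
    flank: int = DEFAULT_TSS_FLANK,
    chrom_length: int | None = None,
) -> tuple[int, int]:
    """Genomic half-open interval for one anchor kind, clamped to the chromosome.

    ``tss``: [TSS - flank, TSS + flank); ``promoter``: the ``flank`` bp
    upstream of the TSS in transcription orientation; ``body``: [txStart,
    txEnd).
    """
    if kind == "tss":
        lo, hi = gene.tss - flank, gene.tss + flank
    elif kind == "promoter":
        if gene.strand == "+":
            lo, hi = gene.tss - flank, gene.tss
        else:
            lo, hi = gene.tss, gene.tss + flank
    elif kind == "body":
        lo, hi = gene.tx_start, gene.tx_end
    else:
        raise ValueError(f"unknown interval kind {kind!r}")
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    if hi <= lo:
        raise ValueError(f"{gene.transcript_id}: empty {kind} interval")
    return lo, hi


def interval_occupancy(
    sample: MidpointSample,
    chrom: str,
    start: int,
    end: int,
    scale: int = NORMALIZATION_SCALE,
) -> float:
    """Depth- and length-normalized midpoint count over ``[start, end)``."""
    if end <= start:
        raise ValueError("zero-length interval")
    if sample.total <= 0:
        raise ValueError("sample has no mapped reads")
    length_kb = (end - start) / 1000.0
    return sample.count(chrom, start, end) * scale / (sample.total * length_kb)


def interval_matrix(
    samples: Mapping[str, MidpointSample],
    genes: Sequence[GeneRecord],
    interval_kind: str = "tss",
    flank: int = DEFAULT_TSS_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
    scale: int = NORMALIZATION_SCALE,
) -> pd.DataFrame:
    """Occupancy matrix for arbitrary sample keys (one column per key)."""
    data: dict[str, list[float]] = {}
    intervals = [
        gene_interval(
            g, interval_kind, flank, chrom_sizes.get(g.chrom) if chrom_sizes else None
        )
        for g in genes
    ]
    for key, sample in samples.items():
        data[key] = [
            interval_occupancy(sample, g.chrom, lo, hi, scale)
            for g, (lo, hi) in zip(genes, intervals)
        ]
    out = pd.DataFrame(data, index=[g.transcript_id for g in genes])
    out.attrs["interval_kind"] = interval_kind
    return out


def build_occupancy_matrix(
    samples: Mapping[tuple[str, str], MidpointSample],
    genes: Sequence[GeneRecord],
    interval_kind: str = "tss",
    flank: int = DEFAULT_TSS_FLANK,
    chrom_sizes: Mapping[str, int] | None = None,
    scale: int = NORMALIZATION_SCALE,
) -> pd.DataFrame:
    """Genes x (mark, stage) occupancy matrix in canonical column order.

    ``samples`` must provide one :class:`MidpointSample` per (mark, stage)
    of the 2-mark x 4-stage design; a missing sample is an error.
    """
    missing = [(m, s) for m in MARKS for s in STAGES if (m, s) not in samples]
    if missing:
        raise ValueError(f"missing samples for: {missing}")
    keyed = {f"{m}_{s}": samples[(m, s)] for m in MARKS for s in STAGES}
    matrix = interval_matrix(keyed, genes, interval_kind, flank, chrom_sizes, scale)
    return matrix[matrix_columns()]
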