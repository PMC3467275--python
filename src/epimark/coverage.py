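"""Fragment-midpoint coverage: 100-bp binned tracks, depth normalization,
and TSS metaprofiles with LOWESS smoothing.

Each uniquely mapped read stands in for a sequencing fragment assumed to be
190 bp long; the fragment midpoint (read start + 95 on the plus strand,
read end - 95 on the minus strand) is the unit of evidence for all
downstream counting.  Tracks count midpoints per 100-bp half-open bin and
are depth-normalized to reads per 5,000,000 mapped reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io_formats import GeneRecord, MappedRead

#: depth-normalization scale: values are per this many mapped reads
NORMALIZATION_SCALE = 5_000_000

DEFAULT_FRAGMENT_LEN = 190
DEFAULT_BIN_SIZE = 100


def fragment_midpoint(
    read: MappedRead,
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
    chrom_length: int | None = None,
) -> int:
    """Midpoint of the inferred fragment, clamped to ``[0, chrom_length)``.

    Plus-strand reads extend downstream from ``start``; minus-strand reads
    extend upstream from ``end``.  ``fragment_len // 2`` is used exactly
    (95 for the default 190-bp fragment).
    """
    half = fragment_len // 2
    if read.strand == "+":
        mid = read.start + half
    else:
        mid = read.end - half
    if mid < 0:
        mid = 0
    if chrom_length is not None and mid >= chrom_length:
        mid = chrom_length - 1
    return mid


@dataclass
class MidpointSample:
    """Sorted fragment midpoints per chromosome plus the library size."""

    midpoints: dict[str, np.ndarray]
    total: int

    def count(self, chrom: str, start: int, end: int) -> int:
        """Number of midpoints in the half-open interval ``[start, end)``."""
        mids = self.midpoints.get(chrom)
        if mids is None:
            return 0
        return int(np.searchsorted(mids, end, "left") - np.searchsorted(mids, start, "left"))


def fragment_midpoints(
    reads: Iterable[MappedRead],
    chrom_sizes: Mapping[str, int],
    fragment_len: int = DEFAULT_FRAGMENT_LEN,
) -> MidpointSample:
    """Convert reads to a sorted per-chromosome midpoint sample."""
    per_chrom: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    total = 0
    for read in reads:
        length = chrom_sizes.get(read.chrom)
        if length is None:
            continue
        per_chrom[read.chrom].append(fragment_midpoint(read, fragment_len, length))
        total += 1
    return MidpointSample(
        midpoints={c: np.sort(np.asarray(m, dtype=np.int64)) for c, m in per_chrom.items()},
        total=total,
    )


@dataclass
class BinnedTrack:
    """Per-chromosome midpoint counts in fixed-width half-open bins.

    Bin ``i`` covers ``[i * bin_size, (i + 1) * bin_size)``.  Raw tracks
    hold integer counts; normalized tracks hold counts scaled by
    ``NORMALIZATION_SCALE / total_mapped_reads``.
    """

    counts: dict[str, np.ndarray]
    bin_size: int = DEFAULT_BIN_SIZE
    total_mapped_reads: int = 0
    normalized: bool = False

    @property
    def n_bins(self) -> int:
        return sum(len(c) for c in self.counts.values())

    def genome_length(self) -> int:
        return self.n_bins * self.bin_size


def bin_midpoints(
    sample: MidpointSample,
    chrom_sizes: Mapping[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinnedTrack:
    """Count midpoints per bin; the total count is conserved."""
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        n_bins = -(-length // bin_size)
        mids = sample.midpoints.get(chrom)
        if mids is None or len(mids) == 0:
            counts[chrom] = np.zeros(n_bins, dtype=np.int64)
        else:
            counts[chrom] = np.bincount(mids // bin_size, minlength=n_bins).astype(np.int64)
    return BinnedTrack(
        counts=counts,
        bin_size=bin_size,
        total_mapped_reads=sample.total,
        normalized=False,
    )


def normalize_track(track: BinnedTrack, scale: int = NORMALIZATION_SCALE) -> BinnedTrack:
    """Scale bin counts to reads per ``scale`` (default 5e6) mapped reads."""
    if track.total_mapped_reads <= 0:
        raise ValueError("cannot normalize a track with zero mapped reads")
    factor = scale / track.total_mapped_reads
    return replace(
        track,
        counts={c: v * factor for c, v in track.counts.items()},
        normalized=True,
    )


@dataclass
class MetaProfile:
    """Aggregate midpoint density around TSSs, oriented by transcription.

    ``positions`` are offsets of bin centers relative to the TSS (negative
    = upstream).  ``density`` sums to 1 over the profile.
    """

    positions: np.ndarray
    density: np.ndarray
    counts: np.ndarray
    n_tss: int
    bin_size: int = DEFAULT_BIN_SIZE
    smoothed: np.ndarray | None = field(default=None)


def tss_metaprofile(
    sample: MidpointSample,
    genes: Sequence[GeneRecord],
    flank: int = 5000,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> MetaProfile:
    """Aggregate midpoints in TSS +/- ``flank`` over all transcripts.

    Minus-strand windows are reversed so that positive offsets always point
    downstream of transcription.  Overlapping windows from splice variants
    each contribute independently.  Each offset-bin count is divided by the
    total count over all windows; if no midpoint falls in any window the
    normalization is undefined and an error is raised.

    ``bin_size=1`` gives the per-bp variant of the profile.
    """
    if not genes:
        raise ValueError("need at least one gene")
    if flank % bin_size:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    counts = np.zeros(n_bins, dtype=np.int64)
    for gene in genes:
        mids = sample.midpoints.get(gene.chrom)
        if mids is None or len(mids) == 0:
            continue
        tss = gene.tss
        if gene.strand == "+":
            lo = np.searchsorted(mids, tss - flank, "left")
            hi = np.searchsorted(mids, tss + flank, "left")
            offsets = mids[lo:hi] - tss
        else:
            lo = np.searchsorted(mids, tss - flank, "right")
            hi = np.searchsorted(mids, tss + flank, "right")
            offsets = tss - mids[lo:hi]
        counts += np.bincount((offsets + flank) // bin_size, minlength=n_bins)
    total = int(counts.sum())
    if total == 0:
        raise ValueError("no midpoints in any TSS window; profile normalization undefined")
    positions = np.arange(-flank, flank, bin_size) + bin_size // 2
    return MetaProfile(
        positions=positions,
        density=counts / total,
        counts=counts,
        n_tss=len(genes),
        bin_size=bin_size,
    )


def lowess_smooth(
    values: np.ndarray,
    span: float = 0.05,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Locally weighted linear regression over the profile.

    ``span`` is the LOWESS bandwidth as a fraction of the data.  The
    smoother reproduces constants and straight lines exactly.
    """
    if not 0.0 < span <= 1.0:
        raise ValueError(f"span must be in (0, 1], got {span}")
    values = np.asarray(values, dtype=float)
    if len(values) < 10:
        raise ValueError("need at least 10 positions to smooth")
    x = np.arange(len(values), dtype=float) if positions is None else np.asarray(positions, float)
    return _sm_lowess(values, x, frac=span, return_sorted=False)


def smooth_profile(profile: MetaProfile, span: float = 0.05) -> MetaProfile:
    """Return the profile with its ``smoothed`` curve filled in."""
    smoothed = lowess_smooth(profile.density, span=span, positions=profile.positions)
    return replace(profile, smoothed=smoothed)


def profile_peaks(
    profile: MetaProfile,
    prominence_frac: float = 0.1,
    min_separation: int = 500,
) -> np.ndarray:
    """Offsets (bp) of local maxima of the smoothed curve.

    A maximum counts as a peak only if its prominence exceeds
    ``prominence_frac`` of the smoothed curve's dynamic range (suppressing
    sampling-noise wiggles in the profile tails) and it is at least
    ``min_separation`` bp from any higher maximum (twin summits on one
    enrichment feature count once).
    """
    if profile.smoothed is None:
        raise ValueError("profile has no smoothed curve; call smooth_profile first")
    y = profile.smoothed
    prominence = prominence_frac * (float(y.max()) - float(y.min()))
    distance = max(1, -(-min_separation // profile.bin_size))
    idx, _ = find_peaks(y, prominence=prominence, distance=distance)
    return profile.positions[idx]
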