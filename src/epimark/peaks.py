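"""Poisson sliding-window enrichment calling with mock-IP control filtering.

Every window along each chromosome (default 100-bp windows at a 100-bp
pace) is tested against a Poisson null whose rate is the genome-wide (or
per-chromosome) mean midpoint count per window.  Windows with an upper-tail
probability strictly below the threshold (default 1e-5) are significant;
overlapping or abutting significant windows merge into enriched regions.
A region is discarded if the anti-GFP (mock IP) control is itself
significantly enriched over the same span.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import poisson

from .coverage import BinnedTrack


@dataclass(frozen=True)
class CallerConfig:
    window: int = 100
    step: int = 100
    p_threshold: float = 1e-5
    lambda_mode: str = "global"  # or "per_chromosome"

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0, 1)")
        if self.lambda_mode not in ("global", "per_chromosome"):
            raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")


@dataclass(frozen=True)
class SignificantWindow:
    chrom: str
    start: int
    end: int
    count: int
    p: float


@dataclass(frozen=True)
class EnrichedRegion:
    chrom: str
    start: int
    end: int
    min_p: float
    max_count: int
    n_windows: int


def estimate_background_rate(track: BinnedTrack, cfg: CallerConfig):
    """Expected midpoints per window under the background model.

    Global mode: (total midpoints) / (genome length / window) — i.e. the
    genome-wide per-bp rate times the window size.  Per-chromosome mode
    returns a dict of per-chromosome rates.
    """
    if track.n_bins == 0:
        raise ValueError("empty track")
    if cfg.lambda_mode == "per_chromosome":
        return {
            chrom: float(counts.sum()) * cfg.window / (len(counts) * track.bin_size)
            for chrom, counts in track.counts.items()
        }
    total = sum(float(c.sum()) for c in track.counts.values())
    return total * cfg.window / track.genome_length()


def poisson_upper_tail(k: int, lam: float) -> float:
    """P(X >= k) for X ~ Poisson(lam); stable for lam up to ~1e4."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    if k == 0:
        return 1.0
    return float(poisson.sf(k - 1, lam))


def _window_counts(counts: np.ndarray, w_bins: int, s_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Sliding sums of ``w_bins`` consecutive bins at a ``s_bins`` pace."""
    csum = np.concatenate(([0], np.cumsum(counts)))
    starts = np.arange(0, len(counts) - w_bins + 1, s_bins)
    return starts, csum[starts + w_bins] - csum[starts]


def scan_windows(
    track: BinnedTrack,
    cfg: CallerConfig | None = None,
    lam=None,
) -> list[SignificantWindow]:
    """Test every window; return those with p strictly below the threshold.

    ``window`` and ``step`` must be multiples of the track bin size.  The
    background rate is estimated from the track itself unless ``lam`` is
    supplied (scalar, or dict for per-chromosome mode).
    """
    cfg = cfg or CallerConfig()
    if cfg.window % track.bin_size or cfg.step % track.bin_size:
        raise ValueError("window and step must be multiples of the track bin size")
    if track.normalized:
        raise ValueError("scan_windows requires a raw-count track")
    if lam is None:
        lam = estimate_background_rate(track, cfg)
    w_bins = cfg.window // track.bin_size
    s_bins = cfg.step // track.bin_size
    hits: list[SignificantWindow] = []
    for chrom in track.counts:
        counts = track.counts[chrom]
        if len(counts) < w_bins:
            continue
        chrom_lam = lam[chrom] if isinstance(lam, dict) else lam
        if chrom_lam <= 0:
            continue
        starts, k = _window_counts(counts, w_bins, s_bins)
        p = poisson.sf(k - 1, chrom_lam)
        p[k == 0] = 1.0
        sig = p < cfg.p_threshold  # strictly below the threshold
        for i in np.nonzero(sig)[0]:
            start_bp = int(starts[i]) * track.bin_size
            hits.append(
                SignificantWindow(chrom, start_bp, start_bp + cfg.window, int(k[i]), float(p[i]))
            )
    return hits


def merge_windows(
    windows: Sequence[SignificantWindow], cfg: CallerConfig | None = None
) -> list[EnrichedRegion]:
    """Merge overlapping or abutting significant windows into regions.

    With the default window == step, "overlapping windows" degenerates to
    runs of abutting significant windows.  Output is sorted by
    (chromosome, start).
    """
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    regions: list[EnrichedRegion] = []
    cur: list[SignificantWindow] = []

    def _flush() -> None:
        if cur:
            regions.append(
                EnrichedRegion(
                    chrom=cur[0].chrom,
                    start=cur[0].start,
                    end=max(w.end for w in cur),
                    min_p=min(w.p for w in cur),
                    max_count=max(w.count for w in cur),
                    n_windows=len(cur),
                )
            )

    for w in ordered:
        if cur and w.chrom == cur[-1].chrom and w.start <= max(x.end for x in cur):
            cur.append(w)
        else:
            _flush()
            cur = [w]
    _flush()
    return regions


def filter_by_control(
    regions: Sequence[EnrichedRegion],
    control_track: BinnedTrack,
    cfg: CallerConfig | None = None,
    control_lam: float | None = None,
) -> list[EnrichedRegion]:
    """Drop regions that are also significantly enriched in the control.

    The control's midpoint count over the region span is tested against the
    control's own background rate scaled to the span length (the pooled
    rate of span/window windows); regions with control p strictly below the
    threshold are removed.
    """
    cfg = cfg or CallerConfig()
    if control_lam is None:
        control_lam = estimate_background_rate(
            control_track, CallerConfig(window=cfg.window, step=cfg.step, p_threshold=cfg.p_threshold)
        )
        if isinstance(control_lam, dict):  # pooled span test uses a scalar rate
            raise ValueError("per-chromosome control rates are not supported; pass control_lam")
    kept: list[EnrichedRegion] = []
    bs = control_track.bin_size
    for region in regions:
        counts = control_track.counts.get(region.chrom)
        if counts is None:
            kept.append(region)
            continue
        k = int(counts[region.start // bs : -(-region.end // bs)].sum())
        lam_span = control_lam * (region.end - region.start) / cfg.window
        if poisson_upper_tail(k, lam_span) < cfg.p_threshold:
            continue
        kept.append(region)
    return kept


def call_enriched_regions(
    track: BinnedTrack,
    control_track: BinnedTrack | None = None,
    cfg: CallerConfig | None = None,
) -> list[EnrichedRegion]:
    """Scan, merge, and (when a control is given) control-filter."""
    cfg = cfg or CallerConfig()
    regions = merge_windows(scan_windows(track, cfg), cfg)
    if control_track is not None:
        regions = filter_by_control(regions, control_track, cfg)
    return regions
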