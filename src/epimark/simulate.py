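"""Synthetic ChIP-seq study generator.

Emulates the study design end to end: a small multi-chromosome genome with
non-overlapping genes, and seeded read sets for 2 histone marks (H3K4me2,
H3K27me3) x 4 developmental stages (E17.5, PN1, PN7, PN15) x 2 genotypes
(wt, rd1) plus one anti-GFP mock-IP control per stage.  Five gene classes
are planted at known loci:

========== ============================ ===========================
class      H3K4me2 TSS folds (by stage) H3K27me3 TSS folds
========== ============================ ===========================
ROD        0, 0, 4, 8 (+ gene body)     0, 0, 0, 0
NONROD     1, 1, 1, 1                   6, 6, 6, 6 (+ gene body)
UBIQ       8, 8, 8, 8                   0, 0, 0, 0
SILENT     0, 0, 0, 0                   0, 0, 0, 0
DOWN       8, 6, 2, 0                   0, 1, 2, 4
========== ============================ ===========================

Per-bin counts are Poisson with intensity lambda_bg * (1 + fold * shape).
The H3K4me2 TSS shape is bimodal (two Gaussian bumps, sigma 300 bp, at
+/- 1 kb around the TSS); H3K27me3 and gene-body contributions are flat
domains.  Shapes are scaled to mean 1 over their window, so a fold-f gene
holds (1+f) times the background count in its TSS window on average.  In
the rd1 genotype the whole H3K4me2 coverage over ROD-class gene footprints
is multiplied by ``rd1_rod_scale``, emulating the loss of rod
photoreceptors.  Reads are placed so the 190-bp fragment-midpoint rule
recovers the generating bin exactly.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .coverage import BinnedTrack, MidpointSample, fragment_midpoints
from .io_formats import (
    GeneRecord,
    genes_to_dataframe,
    read_bed_reads,
    read_chrom_sizes,
    read_refgene,
    write_chrom_sizes,
)
from .occupancy import GENOTYPES, MARKS, STAGES

CLASS_ROD = "ROD"
CLASS_NONROD = "NONROD_RETINAL"
CLASS_UBIQ = "UBIQUITOUS"
CLASS_SILENT = "SILENT"
CLASS_DOWN = "DOWN"
GENE_CLASSES = (CLASS_ROD, CLASS_NONROD, CLASS_UBIQ, CLASS_SILENT, CLASS_DOWN)

# planted fold-over-background per class, by stage order (E17.5, PN1, PN7, PN15)
K4_TSS_FOLDS = {
    CLASS_ROD: (0, 0, 4, 8),
    CLASS_NONROD: (1, 1, 1, 1),
    CLASS_UBIQ: (8, 8, 8, 8),
    CLASS_SILENT: (0, 0, 0, 0),
    CLASS_DOWN: (8, 6, 2, 0),
}
K4_BODY_FOLDS = {
    CLASS_ROD: (0, 0, 4, 8),
    CLASS_NONROD: (0, 0, 0, 0),
    CLASS_UBIQ: (0, 0, 0, 0),
    CLASS_SILENT: (0, 0, 0, 0),
    CLASS_DOWN: (0, 0, 0, 0),
}
K27_TSS_FOLDS = {
    CLASS_ROD: (0, 0, 0, 0),
    CLASS_NONROD: (6, 6, 6, 6),
    CLASS_UBIQ: (0, 0, 0, 0),
    CLASS_SILENT: (0, 0, 0, 0),
    CLASS_DOWN: (0, 1, 2, 4),
}
K27_BODY_FOLDS = {
    CLASS_ROD: (0, 0, 0, 0),
    CLASS_NONROD: (6, 6, 6, 6),
    CLASS_UBIQ: (0, 0, 0, 0),
    CLASS_SILENT: (0, 0, 0, 0),
    CLASS_DOWN: (0, 0, 0, 0),
}

TSS_FOLDS = {"H3K4me2": K4_TSS_FOLDS, "H3K27me3": K27_TSS_FOLDS}
BODY_FOLDS = {"H3K4me2": K4_BODY_FOLDS, "H3K27me3": K27_BODY_FOLDS}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohort.

    Defaults are the packaged fixture: 2 chromosomes of 8 Mb, 50 genes per
    class, background 0.2 midpoints per 100-bp bin, 190-bp fragments,
    36-bp reads, and a 0.4x rod-signal scale for the rd1 genotype.
    """

    n_chrom: int = 2
    chrom_length: int = 8_000_000
    genes_per_class: int = 50
    lambda_bg: float = 0.2
    fragment_len: int = 190
    read_len: int = 36
    bin_size: int = 100
    tss_flank: int = 2500
    bump_offset: int = 1000
    bump_sigma: int = 300
    gene_length_range: tuple[int, int] = (2000, 20000)
    min_gene_gap: int = 15000
    chrom_margin: int = 10000
    rd1_rod_scale: float = 0.4
    seed: int = 0
    classes: tuple[str, ...] = GENE_CLASSES

    def __post_init__(self) -> None:
        if self.lambda_bg <= 0:
            raise ValueError("lambda_bg must be positive")


def _sample_order() -> list[tuple[str, str, str]]:
    return [(m, s, g) for m in MARKS for s in STAGES for g in GENOTYPES]


def _rngs(cfg: SimConfig) -> dict:
    """One independent, seed-stable stream per generated artifact."""
    ss = np.random.SeedSequence(cfg.seed)
    names = ["genome"] + [f"{m}_{s}_{g}" for m, s, g in _sample_order()] + [
        f"GFP_{s}" for s in STAGES
    ]
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def build_genome(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, int], list[GeneRecord], pd.DataFrame]:
    """Genome, annotation and class-truth table.

    Genes are laid out round-robin across chromosomes with alternating
    strands, lengths uniform in ``gene_length_range`` and at least
    ``min_gene_gap`` between neighbours (so +/-5 kb TSS windows never reach
    a neighbour's signal).  Raises if the requested genes do not fit.
    """
    rng = rng or np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    chrom_sizes = {f"chr{i + 1}": cfg.chrom_length for i in range(cfg.n_chrom)}
    n_genes = cfg.genes_per_class * len(cfg.classes)
    genes: list[GeneRecord] = []
    rows: list[dict] = []
    if n_genes == 0:
        return chrom_sizes, genes, pd.DataFrame(
            columns=["transcript_id", "gene_symbol", "chrom", "strand", "class"]
        )
    # interleave classes so every chromosome carries all of them
    class_of = [cfg.classes[i % len(cfg.classes)] for i in range(n_genes)]
    per_chrom = [n_genes // cfg.n_chrom + (1 if i < n_genes % cfg.n_chrom else 0) for i in range(cfg.n_chrom)]
    gene_idx = 0
    for ci, chrom in enumerate(chrom_sizes):
        n = per_chrom[ci]
        if n == 0:
            continue
        lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, size=n)
        avail = cfg.chrom_length - 2 * cfg.chrom_margin
        needed = int(lengths.sum()) + (n - 1) * cfg.min_gene_gap
        if needed > avail:
            raise ValueError(
                f"{n} genes (span {needed} bp) do not fit on {chrom} ({avail} bp usable)"
            )
        extra = rng.random(n)
        extra = np.floor(extra / extra.sum() * (avail - needed)).astype(int)
        pos = cfg.chrom_margin
        for j in range(n):
            pos += int(extra[j])
            tx_start, tx_end = pos, pos + int(lengths[j])
            strand = "+" if gene_idx % 2 == 0 else "-"
            tid = f"TX{gene_idx:04d}"
            genes.append(GeneRecord(tid, f"GENE{gene_idx:04d}", chrom, strand, tx_start, tx_end))
            rows.append(
                {
                    "transcript_id": tid,
                    "gene_symbol": f"GENE{gene_idx:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "class": class_of[gene_idx],
                }
            )
            pos = tx_end + cfg.min_gene_gap
            gene_idx += 1
    truth = pd.DataFrame(rows)
    return chrom_sizes, genes, truth


def _tss_shape(cfg: SimConfig, mark: str) -> np.ndarray:
    """Per-bin shape over the TSS window, scaled to mean 1.

    H3K4me2: two Gaussian bumps at +/- ``bump_offset``; H3K27me3: flat.
    """
    n = 2 * cfg.tss_flank // cfg.bin_size
    if mark == "H3K27me3":
        return np.ones(n)
    centers = np.arange(n) * cfg.bin_size + cfg.bin_size / 2 - cfg.tss_flank
    s2 = 2.0 * cfg.bump_sigma**2
    shape = np.exp(-((centers - cfg.bump_offset) ** 2) / s2) + np.exp(
        -((centers + cfg.bump_offset) ** 2) / s2
    )
    return shape / shape.mean()


def sample_intensity(
    cfg: SimConfig,
    mark: str,
    stage: str,
    genotype: str,
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneRecord],
    truth: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Expected midpoints per bin for one (mark, stage, genotype) library."""
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}")
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    stage_i = STAGES.index(stage)
    intensity = {
        chrom: np.full(-(-length // cfg.bin_size), cfg.lambda_bg)
        for chrom, length in chrom_sizes.items()
    }
    klass = dict(zip(truth["transcript_id"], truth["class"])) if len(truth) else {}
    shape = _tss_shape(cfg, mark)
    for gene in genes:
        cls = klass.get(gene.transcript_id)
        if cls is None:
            raise ValueError(f"no class for {gene.transcript_id}")
        if cls not in TSS_FOLDS[mark]:
            raise ValueError(f"unknown gene class {cls!r}")
        tss_fold = TSS_FOLDS[mark][cls][stage_i]
        body_fold = BODY_FOLDS[mark][cls][stage_i]
        arr = intensity[gene.chrom]
        if tss_fold:
            b0 = (gene.tss - cfg.tss_flank) // cfg.bin_size
            arr[b0 : b0 + len(shape)] += cfg.lambda_bg * tss_fold * shape
        if body_fold:
            lo, hi = gene.tx_start // cfg.bin_size, -(-gene.tx_end // cfg.bin_size)
            arr[lo:hi] += cfg.lambda_bg * body_fold
        if genotype == "rd1" and mark == "H3K4me2" and cls == CLASS_ROD:
            lo = min((gene.tss - cfg.tss_flank) // cfg.bin_size, gene.tx_start // cfg.bin_size)
            hi = max(-(-(gene.tss + cfg.tss_flank) // cfg.bin_size), -(-gene.tx_end // cfg.bin_size))
            arr[lo:hi] *= cfg.rd1_rod_scale
    return intensity


def _reads_from_counts(
    counts: Mapping[str, np.ndarray],
    chrom_sizes: Mapping[str, int],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """BED6 rows whose 190-bp midpoint rule recovers the generating bin."""
    half = cfg.fragment_len // 2
    frames = []
    for chrom, c in counts.items():
        total = int(c.sum())
        if total == 0:
            continue
        length = chrom_sizes[chrom]
        bins = np.repeat(np.nonzero(c)[0], c[np.nonzero(c)[0]])
        mids = bins * cfg.bin_size + rng.integers(0, cfg.bin_size, size=total)
        strands = rng.integers(0, 2, size=total)  # 0 = '+', 1 = '-'
        # a '+' read needs mid >= half; a '-' read needs mid + half <= length
        strands = np.where(mids < half, 1, strands)
        strands = np.where(mids + half > length, 0, strands)
        starts = np.where(strands == 0, mids - half, mids + half - cfg.read_len)
        ends = starts + cfg.read_len
        order = np.argsort(starts, kind="stable")
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts[order],
                    "end": ends[order],
                    "name": [f"r{chrom}_{i}" for i in range(total)],
                    "score": 0,
                    "strand": np.where(strands[order] == 0, "+", "-"),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    return pd.concat(frames, ignore_index=True)


def simulate_mark_reads(
    cfg: SimConfig,
    mark: str,
    stage: str,
    genotype: str,
    chrom_sizes: Mapping[str, int],
    genes: Sequence[GeneRecord],
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate one IP library as a BED6 read table."""
    intensity = sample_intensity(cfg, mark, stage, genotype, chrom_sizes, genes, truth)
    counts = {chrom: rng.poisson(lam) for chrom, lam in intensity.items()}
    return _reads_from_counts(counts, chrom_sizes, cfg, rng)


def simulate_control(
    cfg: SimConfig,
    stage: str,
    chrom_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pure-background mock-IP (anti-GFP) library: Poisson(lambda_bg) everywhere."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    counts = {
        chrom: rng.poisson(cfg.lambda_bg, size=-(-length // cfg.bin_size))
        for chrom, length in chrom_sizes.items()
    }
    return _reads_from_counts(counts, chrom_sizes, cfg, rng)


def planted_peak_track(
    chrom_sizes: Mapping[str, int],
    peaks: Sequence[tuple[str, int, int, float]],
    lambda_bg: float,
    rng: np.random.Generator,
    bin_size: int = 100,
) -> BinnedTrack:
    """Raw track with flat fold-enrichments planted on Poisson background.

    ``peaks`` are (chrom, start, end, fold) tuples; inside a peak the bin
    intensity is lambda_bg * (1 + fold).
    """
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_sizes.items():
        lam = np.full(-(-length // bin_size), lambda_bg)
        for pc, start, end, fold in peaks:
            if pc == chrom:
                lam[start // bin_size : -(-end // bin_size)] += lambda_bg * fold
        counts[chrom] = rng.poisson(lam)
    total = int(sum(c.sum() for c in counts.values()))
    return BinnedTrack(counts=counts, bin_size=bin_size, total_mapped_reads=total)


def _write_bed(reads: pd.DataFrame, path: Path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


def _write_refgene(genes: Sequence[GeneRecord], path: Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fields = [
                "0", g.transcript_id, g.chrom, g.strand, str(g.tx_start), str(g.tx_end),
                str(g.tx_start), str(g.tx_end), "1", f"{g.tx_start},", f"{g.tx_end},",
                "0", g.gene_symbol, "cmpl", "cmpl", "0,",
            ]
            fh.write("\t".join(fields) + "\n")


def emit_fixture_set(cfg: SimConfig, outdir: str | Path) -> dict:
    """Write the full fixture: genome, annotation, truth, all read files.

    Produces 2 marks x 4 stages x 2 genotypes IP libraries plus 4 anti-GFP
    controls (20 BED files), ``chrom.sizes``, ``refGene.txt``,
    ``truth.tsv`` and a ``manifest.yaml`` enumerating everything.  A fixed
    seed yields byte-identical output.  On failure, files created by this
    call are removed.
    """
    outdir = Path(outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        rngs = _rngs(cfg)
        chrom_sizes, genes, truth = build_genome(cfg, rngs["genome"])
        write_chrom_sizes(chrom_sizes, outdir / "chrom.sizes")
        _write_refgene(genes, outdir / "refGene.txt")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        manifest: dict = {
            "chrom_sizes": "chrom.sizes",
            "genes": "refGene.txt",
            "truth": "truth.tsv",
            "fragment_len": cfg.fragment_len,
            "bin_size": cfg.bin_size,
            "samples": [],
            "controls": [],
        }
        for mark, stage, genotype in _sample_order():
            name = f"{mark}_{stage}_{genotype}.bed"
            reads = simulate_mark_reads(
                cfg, mark, stage, genotype, chrom_sizes, genes, truth,
                rngs[f"{mark}_{stage}_{genotype}"],
            )
            _write_bed(reads, outdir / name)
            manifest["samples"].append(
                {"mark": mark, "stage": stage, "genotype": genotype, "path": name}
            )
        for stage in STAGES:
            name = f"GFP_{stage}.bed"
            _write_bed(simulate_control(cfg, stage, chrom_sizes, rngs[f"GFP_{stage}"]), outdir / name)
            manifest["controls"].append({"stage": stage, "path": name})
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        return manifest
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        raise


@dataclass
class Fixture:
    """A loaded fixture: genome, annotation, truth, and midpoint samples."""

    chrom_sizes: dict[str, int]
    genes: list[GeneRecord]
    truth: pd.DataFrame
    samples: dict[tuple[str, str, str], MidpointSample]
    controls: dict[str, MidpointSample]
    fragment_len: int = 190
    bin_size: int = 100

    def genotype_samples(self, genotype: str) -> dict[tuple[str, str], MidpointSample]:
        return {
            (m, s): smp for (m, s, g), smp in self.samples.items() if g == genotype
        }

    def truth_ids(self, klass: str) -> list[str]:
        return self.truth.loc[self.truth["class"] == klass, "transcript_id"].tolist()


def load_fixture(manifest_path: str | Path) -> Fixture:
    """Read an emitted fixture back through the standard-format readers."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    chrom_sizes = read_chrom_sizes(base / manifest["chrom_sizes"])
    genes = read_refgene(base / manifest["genes"])
    truth = pd.read_csv(base / manifest["truth"], sep="\t")
    frag = int(manifest.get("fragment_len", 190))
    samples = {}
    for entry in manifest["samples"]:
        reads = read_bed_reads(base / entry["path"], chrom_sizes)
        samples[(entry["mark"], entry["stage"], entry["genotype"])] = fragment_midpoints(
            reads, chrom_sizes, frag
        )
    controls = {}
    for entry in manifest["controls"]:
        reads = read_bed_reads(base / entry["path"], chrom_sizes)
        controls[entry["stage"]] = fragment_midpoints(reads, chrom_sizes, frag)
    return Fixture(
        chrom_sizes=chrom_sizes,
        genes=genes,
        truth=truth,
        samples=samples,
        controls=controls,
        fragment_len=frag,
        bin_size=int(manifest.get("bin_size", 100)),
    )
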