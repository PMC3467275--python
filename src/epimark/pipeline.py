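"""End-to-end pipeline: reads -> tracks -> enriched regions -> occupancy
matrices -> signature labels -> comparisons -> metaprofile.

Configured by a single YAML file pointing at a read manifest (the format
written by :func:`epimark.simulate.emit_fixture_set`) plus parameters.
Reruns with the same config are bit-identical; every stage's parameters
and the input checksums are recorded in ``run_log.yaml``.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coverage, io_formats, occupancy, peaks, signatures
from .signatures import SignatureThresholds
from .simulate import Fixture, load_fixture


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    manifest: Path
    outdir: Path
    window: int = 100
    step: int = 100
    p_threshold: float = 1e-5
    lambda_mode: str = "global"
    tss_flank: int = 2500
    profile_flank: int = 5000
    profile_span: float = 0.05
    thresholds: SignatureThresholds = field(default_factory=SignatureThresholds)
    use_body_rule: bool = False
    write_tracks: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = SignatureThresholds(**raw.pop("thresholds", {}))
        manifest = (path.parent / raw.pop("manifest")).resolve()
        outdir = Path(raw.pop("outdir"))
        if not outdir.is_absolute():
            outdir = path.parent / outdir
        return cls(manifest=manifest, outdir=outdir, thresholds=thr, **raw)


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(config: PipelineConfig) -> dict:
    """Check that every referenced input exists before any compute."""
    manifest_path = Path(config.manifest)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    base = manifest_path.parent
    paths = [manifest["chrom_sizes"], manifest["genes"]]
    paths += [e["path"] for e in manifest.get("samples", [])]
    paths += [e["path"] for e in manifest.get("controls", [])]
    missing = [p for p in paths if not (base / p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    stages_present = {e["stage"] for e in manifest.get("controls", [])}
    needed = {e["stage"] for e in manifest.get("samples", [])}
    if needed - stages_present:
        raise ValueError(f"missing control file for stages: {sorted(needed - stages_present)}")
    return {p: _md5(base / p) for p in paths}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of output paths.

    On failure the partial outputs are kept and a ``failed/`` marker names
    the stage that broke.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "validate"
    try:
        checksums = validate_inputs(config)
        stage = "load"
        fixture = load_fixture(config.manifest)
        outputs: dict[str, str] = {}

        stage = "tracks"
        tracks = {
            key: coverage.bin_midpoints(smp, fixture.chrom_sizes, fixture.bin_size)
            for key, smp in fixture.samples.items()
        }
        control_tracks = {
            s: coverage.bin_midpoints(smp, fixture.chrom_sizes, fixture.bin_size)
            for s, smp in fixture.controls.items()
        }
        if config.write_tracks:
            tracks_dir = outdir / "tracks"
            tracks_dir.mkdir(exist_ok=True)
            for (mark, st, gt), track in tracks.items():
                path = tracks_dir / f"{mark}_{st}_{gt}.bedgraph"
                io_formats.write_bedgraph(coverage.normalize_track(track), path)
                outputs[f"track:{mark}_{st}_{gt}"] = str(path)
            for st, track in control_tracks.items():
                path = tracks_dir / f"GFP_{st}.bedgraph"
                io_formats.write_bedgraph(coverage.normalize_track(track), path)
                outputs[f"track:GFP_{st}"] = str(path)

        stage = "callpeaks"
        cfg = peaks.CallerConfig(
            window=config.window,
            step=config.step,
            p_threshold=config.p_threshold,
            lambda_mode=config.lambda_mode,
        )
        regions_dir = outdir / "regions"
        regions_dir.mkdir(exist_ok=True)
        for (mark, st, gt), track in sorted(tracks.items()):
            regions = peaks.call_enriched_regions(track, control_tracks[st], cfg)
            path = regions_dir / f"{mark}_{st}_{gt}.bed"
            io_formats.write_regions_bed(regions, path)
            outputs[f"regions:{mark}_{st}_{gt}"] = str(path)

        stage = "occupancy"
        matrices: dict[tuple[str, str], pd.DataFrame] = {}
        for genotype in ("wt", "rd1"):
            geno_samples = fixture.genotype_samples(genotype)
            if len(geno_samples) < 8:
                continue
            for kind in occupancy.INTERVAL_KINDS:
                mat = occupancy.build_occupancy_matrix(
                    geno_samples, fixture.genes, kind, config.tss_flank, fixture.chrom_sizes
                )
                matrices[(genotype, kind)] = mat
                path = outdir / f"occupancy_{kind}_{genotype}.tsv"
                io_formats.write_matrix_tsv(mat, path)
                outputs[f"occupancy:{kind}:{genotype}"] = str(path)
        gfp_matrix = occupancy.interval_matrix(
            {f"GFP_{s}": smp for s, smp in fixture.controls.items()},
            fixture.genes,
            "tss",
            config.tss_flank,
            fixture.chrom_sizes,
        )
        gfp_path = outdir / "occupancy_tss_gfp.tsv"
        io_formats.write_matrix_tsv(gfp_matrix, gfp_path)
        outputs["occupancy:tss:gfp"] = str(gfp_path)

        stage = "classify"
        b = signatures.gfp_background(gfp_matrix)
        labels = signatures.classify_signatures(
            matrices[("wt", "tss")],
            b,
            config.thresholds,
            body_matrix=matrices[("wt", "body")],
            use_body=config.use_body_rule,
        )
        labels_path = outdir / "labels_wt.tsv"
        labels.to_csv(labels_path, sep="\t", index_label="gene")
        outputs["labels:wt"] = str(labels_path)

        stage = "compare"
        rod_set = labels.index[labels["label"] == signatures.ROD_SPECIFIC].tolist()
        marked = labels.index[labels["label"] != signatures.NO_MARK].tolist()
        nonrod_set = [g for g in marked if g not in set(rod_set)]
        reports = []
        if len(rod_set) >= 2:
            pb = signatures.compare_promoter_body(
                matrices[("wt", "promoter")], matrices[("wt", "body")], rod_set
            )
            pb.insert(0, "comparison", "promoter_vs_body:rod")
            reports.append(pb)
        if ("rd1", "tss") in matrices:
            for name, gene_set in (("rod", rod_set), ("nonrod", nonrod_set)):
                if len(gene_set) < 2:
                    continue
                res = signatures.compare_genotypes(
                    matrices[("wt", "tss")], matrices[("rd1", "tss")], gene_set, "H3K4me2_PN15"
                )
                reports.append(
                    pd.DataFrame(
                        {
                            "comparison": [f"wt_vs_rd1:{name}"],
                            "mean_wt": [res.test.mean_x],
                            "mean_rd1": [res.test.mean_y],
                            "t": [res.test.t],
                            "df": [res.test.df],
                            "p": [res.test.p],
                            "stars": [res.test.stars],
                            "fold": [res.fold],
                        },
                        index=["H3K4me2_PN15"],
                    )
                )
        comp_path = outdir / "comparisons.tsv"
        if reports:
            pd.concat(reports).to_csv(comp_path, sep="\t", index_label="column")
        else:
            pd.DataFrame().to_csv(comp_path, sep="\t")
        outputs["comparisons"] = str(comp_path)

        stage = "metaprofile"
        profile_rows = []
        for mark in occupancy.MARKS:
            smp = fixture.samples.get((mark, "PN15", "wt"))
            if smp is None or smp.total == 0:
                continue
            prof = coverage.tss_metaprofile(smp, fixture.genes, config.profile_flank)
            prof = coverage.smooth_profile(prof, config.profile_span)
            profile_rows.append(
                pd.DataFrame(
                    {
                        "mark": mark,
                        "offset": prof.positions,
                        "density": prof.density,
                        "smoothed": prof.smoothed,
                    }
                )
            )
        prof_path = outdir / "metaprofile_PN15_wt.tsv"
        if profile_rows:
            pd.concat(profile_rows, ignore_index=True).to_csv(prof_path, sep="\t", index=False)
        else:
            pd.DataFrame(columns=["mark", "offset", "density", "smoothed"]).to_csv(
                prof_path, sep="\t", index=False
            )
        outputs["metaprofile"] = str(prof_path)

        stage = "log"
        log = {
            "parameters": {
                "window": config.window,
                "step": config.step,
                "p_threshold": config.p_threshold,
                "lambda_mode": config.lambda_mode,
                "tss_flank": config.tss_flank,
                "profile_flank": config.profile_flank,
                "profile_span": config.profile_span,
                "thresholds": asdict(config.thresholds),
                "use_body_rule": config.use_body_rule,
            },
            "background_b": float(b),
            "input_checksums": checksums,
            "outputs": {
                k: str(Path(v).relative_to(outdir)) for k, v in sorted(outputs.items())
            },
        }
        with open(outdir / "run_log.yaml", "w") as fh:
            yaml.safe_dump(log, fh, sort_keys=False)
        outputs["log"] = str(outdir / "run_log.yaml")
        return outputs
    except Exception as exc:
        marker_dir = outdir / "failed"
        marker_dir.mkdir(parents=True, exist_ok=True)
        (marker_dir / "stage.txt").write_text(f"{stage}: {exc}\n")
        raise PipelineError(stage, exc) from exc
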