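"""Shared fixtures: the packaged synthetic study, built once per session."""

from __future__ import annotations

import pytest

from epimark import occupancy, signatures
from epimark.pipeline import PipelineConfig, run_pipeline
from epimark.simulate import SimConfig, emit_fixture_set, load_fixture

# fixed cohort seed for the packaged study conditions
FIXTURE_SEED = 20120915


@pytest.fixture(scope="session")
def sim_config() -> SimConfig:
    return SimConfig(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, sim_config):
    outdir = tmp_path_factory.mktemp("fixture")
    emit_fixture_set(sim_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def fixture(fixture_dir):
    return load_fixture(fixture_dir / "manifest.yaml")


@pytest.fixture(scope="session")
def wt_matrices(fixture):
    return {
        kind: occupancy.build_occupancy_matrix(
            fixture.genotype_samples("wt"), fixture.genes, kind, chrom_sizes=fixture.chrom_sizes
        )
        for kind in occupancy.INTERVAL_KINDS
    }


@pytest.fixture(scope="session")
def rd1_tss_matrix(fixture):
    return occupancy.build_occupancy_matrix(
        fixture.genotype_samples("rd1"), fixture.genes, "tss", chrom_sizes=fixture.chrom_sizes
    )


@pytest.fixture(scope="session")
def background_b(fixture):
    gfp = occupancy.interval_matrix(
        {f"GFP_{s}": smp for s, smp in fixture.controls.items()},
        fixture.genes,
        "tss",
        chrom_sizes=fixture.chrom_sizes,
    )
    return signatures.gfp_background(gfp)


@pytest.fixture(scope="session")
def pipeline_outdir(tmp_path_factory, fixture_dir):
    """One full pipeline run over the packaged fixture."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(manifest=fixture_dir / "manifest.yaml", outdir=outdir)
    run_pipeline(config)
    return outdir


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A miniature cohort for fast I/O and orchestration tests."""
    cfg = SimConfig(seed=11, n_chrom=1, chrom_length=1_200_000, genes_per_class=4)
    outdir = tmp_path_factory.mktemp("small_fixture")
    emit_fixture_set(cfg, outdir)
    return outdir
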