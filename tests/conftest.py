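"""Shared fixtures: packaged data paths, synthetic scenarios, pipeline runs."""

from __future__ import annotations

import json
from pathlib import Path

import pytest

from trirec.pipeline import PipelineConfig, SpeciesInputs, run_pipeline
from trirec.synthetic_data import ScenarioConfig, generate_scenario, simulate

DATA_DIR = Path(__file__).resolve().parent.parent / "src" / "trirec" / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def canonical_scenario():
    """The canonical study conditions: 30 clusters across 12 genes."""
    return simulate(ScenarioConfig(seed=1))


@pytest.fixture(scope="session")
def small_scenario():
    """A reduced scenario for fast per-module tests."""
    return simulate(ScenarioConfig(seed=3, n_clusters=8, n_genes=5,
                                   genome_length=60_000, n_mirnas=8))


@pytest.fixture(scope="session")
def scenario_files(tmp_path_factory):
    out = tmp_path_factory.mktemp("scenario")
    cfg = ScenarioConfig(seed=1)
    paths = generate_scenario(cfg, out)
    return paths


@pytest.fixture(scope="session")
def scenario_truth(scenario_files) -> dict:
    return json.loads(Path(scenario_files["truth"]).read_text())


def make_pipeline_config(paths, outdir) -> PipelineConfig:
    return PipelineConfig(
        species_a=SpeciesInputs("cattle_like", str(paths["genome_a"]),
                                str(paths["repeats_a"]), str(paths["genes_a"])),
        species_b=SpeciesInputs("bison_like", str(paths["genome_b"]),
                                str(paths["repeats_b"]), str(paths["genes_b"])),
        mirna_db=str(paths["mirna_db"]),
        outdir=str(outdir),
    )


@pytest.fixture(scope="session")
def pipeline_result(scenario_files, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(make_pipeline_config(scenario_files, outdir))
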