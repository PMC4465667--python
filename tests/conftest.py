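"""Shared fixtures: a session-scoped synthetic dataset and one pipeline run.

The fixture scenario is the reference study condition of the generator
(100 kb reference, two species at 8% divergence, 20 planted conserved block
pairs, two duplicated loci, transcript reads at 5x). The pipeline run on it
uses the read filter matched to the planted divergence (0.85, below the
~0.92 identity the 8% background implies) so that conservation calling, not
read admission, is what the assertions exercise.
"""

import json
from pathlib import Path

import pytest

from anchorprimer.conservation import PipelineConfig
from anchorprimer.pipeline import run_pipeline
from anchorprimer.synthetic import SimulationSpec, simulate_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def sim_paths(tmp_path_factory) -> dict:
    outdir = tmp_path_factory.mktemp("fixture")
    spec = SimulationSpec(rng_seed=FIXTURE_SEED)
    return simulate_fixture(spec, outdir)


@pytest.fixture(scope="session")
def sim_truth(sim_paths) -> dict:
    return json.loads(Path(sim_paths["truth_json"]).read_text())


@pytest.fixture(scope="session")
def fixture_config() -> PipelineConfig:
    return PipelineConfig(min_identity=0.85)


@pytest.fixture(scope="session")
def pipeline_run(sim_paths, fixture_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline_out")
    manifest = run_pipeline(
        fixture_config,
        sim_paths["genome"],
        {sp: v["sam"] for sp, v in sim_paths["species"].items()},
        sim_paths["gff3"],
        outdir,
    )
    return {"outdir": Path(outdir), "manifest": manifest}
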