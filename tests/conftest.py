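import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from methylseed import SimulationConfig, generate_genome, simulate_scenario
from methylseed.pipeline import PipelineConfig, run_pipeline


def make_records(rows):
    """Cytosine table from (chrom, pos, strand, meth, unmeth, context) rows."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "meth", "unmeth", "context"]
    )
    df["tricontext"] = df["context"].map({"CG": "CGA", "CHG": "CAG", "CHH": "CAT"})
    return df


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(seed=3, n_genes=200, chrom_length=600_000, n_tes_per_class=25)


@pytest.fixture(scope="session")
def small_genome(small_config):
    return generate_genome(small_config)


@pytest.fixture(scope="session")
def scenario_dir(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("scenario")
    simulate_scenario(small_config, outdir)
    return outdir


@pytest.fixture(scope="session")
def pipeline_run(scenario_dir, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    config = PipelineConfig(str(scenario_dir), str(outdir), seed=1)
    outputs = run_pipeline(config)
    return outdir, outputs


@pytest.fixture(scope="session")
def default_scenario(tmp_path_factory):
    """The generator's default desk-scale study scenario plus a full run."""
    config = SimulationConfig(seed=0)
    outdir = tmp_path_factory.mktemp("default_scenario")
    genome = simulate_scenario(config, outdir)
    rundir = tmp_path_factory.mktemp("default_run")
    outputs = run_pipeline(PipelineConfig(str(outdir), str(rundir), seed=0))
    return genome, outputs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
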