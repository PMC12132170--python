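import warnings

import numpy as np
import pandas as pd
import pytest

from agechrom.io import PipelineConfig
from agechrom.pipeline import run_pipeline
from agechrom.simulate import SimulationParams, simulate_all

warnings.filterwarnings("ignore", category=UserWarning)


SMALL_PARAMS = SimulationParams(
    n_mice_per_group=8,
    tissues=("kidney",),
    n_cell_types=8,
    n_peaks=400,
    n_genes=100,
    n_chroms=2,
    chrom_length=4_000_000,
    total_cells_per_sample=400,
)


@pytest.fixture(scope="session")
def fixture_run(tmp_path_factory):
    """A small complete synthetic study with the full pipeline run once."""
    run_dir = tmp_path_factory.mktemp("fixture") / "run"
    truth = simulate_all(run_dir, seed=11, params=SMALL_PARAMS)
    run_pipeline(run_dir, PipelineConfig(seed=11))
    return run_dir, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_peaks():
    """Five fixed-width peaks on two chromosomes with summits and scores."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2"],
            "start": [750, 950, 1350, 100, 900],
            "end": [1251, 1451, 1851, 601, 1401],
            "summit": [1000, 1200, 1600, 350, 1150],
            "score": [10.0, 8.0, 5.0, 3.0, 7.0],
            "name": ["a", "b", "c", "d", "e"],
        }
    )
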