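import datetime as dt

import numpy as np
import pytest

from rsfpipe.design import AggregationScheme, default_schemes
from rsfpipe.flowlines import FlowlineSet
from rsfpipe.pipeline import PipelineConfig, SyntheticStudyConfig, run_full
from rsfpipe.rasters import LandCoverRaster
from rsfpipe.synthetic import generate_flowlines, generate_landscape


@pytest.fixture(scope="session")
def h1_scheme() -> AggregationScheme:
    return next(s for s in default_schemes() if s.name == "H1")


@pytest.fixture(scope="session")
def small_landscape() -> LandCoverRaster:
    return generate_landscape(60, 60, 30.0, patch_scale=3.0, seed=5)


@pytest.fixture(scope="session")
def small_flowlines(small_landscape) -> FlowlineSet:
    return generate_flowlines(small_landscape.extent, 3, seed=5)


@pytest.fixture(scope="session")
def tiny_config() -> PipelineConfig:
    """A scaled-down study configuration for end-to-end tests."""
    cfg = PipelineConfig(master_seed=7)
    cfg.synthetic = SyntheticStudyConfig(
        n_rows=120, n_cols=120, n_individuals=6, home_radius=900.0,
        n_late_start=1, n_early_end=1,
    )
    return cfg


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    """One shared end-to-end pipeline run on the scaled-down study."""
    return run_full(tiny_config)
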