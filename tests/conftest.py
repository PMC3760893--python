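import numpy as np
import pytest

from brainevo import (
    EvolutionParams,
    ExperimentConfig,
    RegionAtlas,
    SyntheticCohortConfig,
    generate_atlas,
)


@pytest.fixture(scope="session")
def atlas90():
    return generate_atlas(90, seed=1)


@pytest.fixture()
def atlas12():
    return generate_atlas(12, seed=7)


@pytest.fixture()
def line_atlas():
    """Three nodes on a line at 0 / 50 / 100 mm."""
    coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0], [100.0, 0.0, 0.0]])
    return RegionAtlas(labels=("a", "b", "c"), coords=coords)


@pytest.fixture()
def small_experiment_config():
    """A scaled-down experiment that runs in seconds."""
    cohort = SyntheticCohortConfig(
        n_healthy=4,
        n_ad=3,
        n_regions=30,
        n_timepoints=80,
        healthy_density=100.0,
        ad_density=70.0,
        ad_block_size=None,
    )
    evolution = EvolutionParams(n_steps=5)
    return ExperimentConfig(cohort=cohort, evolution=evolution).with_seed(5)
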