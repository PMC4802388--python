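import numpy as np
import pytest

from lobeconn.pipeline import RunConfig, build_connectomes, preprocess_cohort
from lobeconn.synth import GeneratorConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_generator_config(seed: int = 7, **overrides) -> GeneratorConfig:
    """A fast, fully-featured cohort: 12 regions / 2 modules, short scans."""
    defaults = dict(
        n_rois=12,
        n_modules=2,
        n_timepoints=80,
        n_sf_pre=4,
        n_nsf_pre=3,
        n_sf_post=3,
        n_nsf_post=2,
        n_damaged_range=(1, 2),
        rng_seed=seed,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def tiny_run_config(seed: int = 7, **overrides) -> RunConfig:
    defaults = dict(
        cohort=tiny_generator_config(seed),
        cost=0.30,
        cost_grid_start=0.30,
        cost_grid_stop=0.50,
        cost_grid_step=0.05,
        n_null=2,
        random_reps=5,
        rng_seed=seed,
    )
    defaults.update(overrides)
    return RunConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_cohort():
    return simulate_cohort(tiny_generator_config())


@pytest.fixture(scope="session")
def tiny_processed(tiny_cohort):
    config = tiny_run_config()
    processed, fd = preprocess_cohort(tiny_cohort, config)
    return processed, fd


@pytest.fixture(scope="session")
def tiny_connectomes(tiny_cohort, tiny_processed):
    processed, _ = tiny_processed
    return build_connectomes(processed, tiny_cohort.parcellation)
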