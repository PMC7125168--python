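import numpy as np
import pytest

from connectoml import PipelineConfig, study_spec


@pytest.fixture(scope="session")
def light_config() -> PipelineConfig:
    """A computationally light pipeline configuration for property tests.

    Same procedure, smaller forests / fewer folds / fewer permutations —
    used where a property (leakage, calibration, monotonicity) is invariant
    to problem size.
    """
    return PipelineConfig(rf_trees=100, k_folds=5, n_permutations=19, grid_folds=3)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study: 12+12 subjects, 20 regions, strong effect."""
    return study_spec(
        seed=7, n_planted=8, effect_size=2.0, n_regions=20, n_group1=12, n_group2=12
    )


def make_toy_dataset(seed=0, n_regions=12, n1=10, n2=10, n_planted=4, d=0.0, band="Alpha"):
    spec = study_spec(
        seed=seed,
        n_planted=n_planted,
        effect_size=d,
        n_regions=n_regions,
        n_group1=n1,
        n_group2=n2,
    )
    from connectoml import generate_edge_dataset

    return spec, generate_edge_dataset(spec, band)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
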