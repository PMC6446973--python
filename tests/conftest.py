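import numpy as np
import pytest

from chocoforest.height_map import EnsembleConfig
from chocoforest.pipeline import PipelineConfig, run_pipeline
from chocoforest.simulate import (
    ClusterDesign,
    SimulationConfig,
    sample_scenes,
    simulate_landscape,
    simulate_plots,
)


@pytest.fixture(scope="session")
def small_truth():
    """A compact 1.5 km x 1.5 km landscape for unit-level checks."""
    return simulate_landscape(SimulationConfig(size=(1500.0, 1500.0), seed=7))


@pytest.fixture(scope="session")
def small_scenes(small_truth):
    return sample_scenes(small_truth, 2, seed=3, lengths=(5000.0,))


@pytest.fixture(scope="session")
def small_inventory(small_truth, small_scenes):
    plots, trees = simulate_plots(
        small_truth, small_scenes, ClusterDesign(), seed=5, n_clusters=2
    )
    return plots, trees


@pytest.fixture(scope="session")
def demo_config():
    """The end-to-end demonstration configuration (6 km x 6 km, 5 scenes)."""
    return PipelineConfig(
        simulation=SimulationConfig(size=(6000.0, 6000.0), seed=11),
        n_scenes=5,
        bootstrap_iterations=8,
        cv_iterations=100,
        rf=EnsembleConfig(n_trees=150, seed=11),
        seed=11,
    )


@pytest.fixture(scope="session")
def demo_result(demo_config):
    """One shared end-to-end pipeline run; several suites assert against it."""
    return run_pipeline(demo_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
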