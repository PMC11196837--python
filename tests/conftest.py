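import numpy as np
import pytest

from beeadmix import LineagePanel, SimulationConfig, simulate_dataset


@pytest.fixture
def small_panel() -> LineagePanel:
    """Three fully diagnostic SNPs, one per lineage."""
    return LineagePanel(
        ["s1", "s2", "s3"],
        np.array(
            [
                [1.0, 0.0, 0.0],
                [0.0, 1.0, 0.0],
                [0.0, 0.0, 1.0],
            ]
        ),
    )


@pytest.fixture
def flat_panel() -> LineagePanel:
    """All lineages share every frequency: zero ancestry information."""
    return LineagePanel(["s1", "s2", "s3"], np.full((3, 3), 0.5))


@pytest.fixture
def sim_dataset():
    cfg = SimulationConfig(seed=7, n_colonies=10, n_apiaries=2)
    return simulate_dataset(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
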