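import numpy as np
import pytest

from gpmix import MarkerMatrix, PhenotypeTable, TraitSpec
from gpmix.simulate import SimulatedTrait, SimulationConfig, simulate_markers


@pytest.fixture
def tiny_markers() -> MarkerMatrix:
    rng = np.random.default_rng(11)
    dosages = rng.integers(0, 3, size=(6, 50)).astype(float)
    return MarkerMatrix(
        [f"L{j}" for j in range(6)], [f"M{k}" for k in range(50)], dosages
    )


@pytest.fixture
def two_trait_specs() -> list[TraitSpec]:
    return [TraitSpec("GY", "continuous"), TraitSpec("Height", "binary")]


@pytest.fixture
def small_phenotypes(two_trait_specs) -> PhenotypeTable:
    lines = ["L0", "L1", "L2", "L0", "L1", "L2"]
    envs = ["A", "A", "A", "B", "B", "B"]
    values = {
        "GY": np.array([1.0, 2.0, 3.0, 2.5, 3.5, 1.5]),
        "Height": np.array([1.0, 2.0, 1.0, 2.0, 1.0, 2.0]),
    }
    return PhenotypeTable(lines, envs, values, two_trait_specs)


@pytest.fixture(scope="session")
def hw_markers() -> MarkerMatrix:
    """Complete Hardy-Weinberg markers for GRM property tests."""
    config = SimulationConfig(n_lines=40, n_markers=300, seed=5)
    return simulate_markers(config)


def make_sim_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_lines=50,
        n_environments=3,
        n_markers=100,
        traits=[
            SimulatedTrait("gy", "continuous", 0.8),
            SimulatedTrait("grade", "ordinal", 0.8, (1 / 3, 2 / 3)),
        ],
        genetic_correlation=np.array([[1.0, 0.8], [0.8, 1.0]]),
        gxe_variance_ratio=0.1,
        env_effect_scale=0.25,
        observed_fraction=1.0,
        seed=20,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)
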