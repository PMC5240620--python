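import numpy as np
import pytest

from dasypop import FineGrid, GridGeometry, SynthSpec, generate_world, worked_example_world


@pytest.fixture
def geom_small():
    """2x2 coarse cells, refinement 3, 1-degree fine pixels at origin (0, 0)."""
    return GridGeometry(0.0, 0.0, 1.0, 3, 6, 6)


@pytest.fixture
def world_small():
    """Default synthetic world: 2x2 coarse cells at refinement 10, 3 countries."""
    return generate_world(SynthSpec(seed=42))


@pytest.fixture
def example_world():
    return worked_example_world()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def grid_from(geometry, values, valid=None):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.ones(values.shape, bool)
    return FineGrid(geometry, values, valid)
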