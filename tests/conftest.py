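import numpy as np
import pytest

from urbanscale import nlcd
from urbanscale.landscape import LandscapeConfig, LandscapeStack, generate_landscape


def uniform_stack(code: int, n: int = 40, cell: float = 60.0) -> LandscapeStack:
    """A stack with a single land-cover class everywhere."""
    return LandscapeStack(
        landcover=np.full((n, n), code, dtype=np.int16),
        pop_density=np.full((n, n), 10.0),
        housing_density=np.full((n, n), 4.0),
        elevation=np.full((n, n), 350.0),
        cell_size=cell,
    )


@pytest.fixture(scope="session")
def forest_stack() -> LandscapeStack:
    return uniform_stack(nlcd.DECIDUOUS_FOREST)


@pytest.fixture(scope="session")
def developed_stack() -> LandscapeStack:
    return uniform_stack(nlcd.DEVELOPED_HIGH)


@pytest.fixture(scope="session")
def mixed_stack() -> LandscapeStack:
    """A moderately urbanized synthetic landscape shared across tests."""
    return generate_landscape(
        LandscapeConfig(extent_m=9000, cell_size=60, seed=11, forest_target=0.58)
    )
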