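import numpy as np
import pytest

from wetbird.grids import GridGeometry, MonthlyWaterStack
from wetbird.synth import LandscapeConfig, PatchSpec


def make_stack(water: np.ndarray, years: list[int], cell_size: float = 30.0) -> MonthlyWaterStack:
    geom = GridGeometry(water.shape[2], water.shape[3], cell_size)
    return MonthlyWaterStack(water=water, years=years, geometry=geom)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_stack(rng):
    """One-year 20x20 stack with iid half-wet months."""
    water = (rng.random((1, 12, 20, 20)) < 0.5).astype(np.uint8)
    return make_stack(water, [2010])


@pytest.fixture
def wet_patch_config():
    """Single always-wet rectangular palustrine patch, 40 years."""
    return LandscapeConfig(
        grid_height=20,
        grid_width=20,
        coarse_factor=5,
        years=(1984, 2023),
        patches=(
            PatchSpec(
                functional_class="palustrine",
                footprint=("rect", 2, 3, 5, 4),
                monthly_flood_profile=(1.0,) * 12,
            ),
        ),
        seed=1,
    )
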