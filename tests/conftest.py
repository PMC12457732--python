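import numpy as np
import pandas as pd
import pytest

from nicheforge import (RasterGrid, RasterStack, SyntheticEnvironmentSpec,
                        VirtualSpeciesSpec, generate_environment,
                        sample_occurrences, true_suitability)


@pytest.fixture(scope="session")
def env_small() -> RasterStack:
    """40x40 synthetic environment, 4 variables, no imposed correlations."""
    return generate_environment(SyntheticEnvironmentSpec(
        n_vars=4, grid_shape=(40, 40), spatial_smoothness=2.0, seed=101))


@pytest.fixture(scope="session")
def strong_species() -> VirtualSpeciesSpec:
    """A virtual species with a narrow, well-identified niche.

    Breadths are ~0.3 of the environmental standard deviation (10), so
    presences are strongly clustered in environmental space and a competent
    model can discriminate them from background.
    """
    return VirtualSpeciesSpec(
        species_id="vs1",
        optima={"env1": 25.0, "env3": 66.0},
        breadths={"env1": 3.0, "env3": 3.0},
        n_presences=100,
        sampling_mode="probabilistic",
        seed=11,
    )


@pytest.fixture(scope="session")
def occurrences_small(env_small, strong_species) -> pd.DataFrame:
    return sample_occurrences(true_suitability(env_small, strong_species), strong_species)


@pytest.fixture
def unit_grid() -> RasterGrid:
    """Simple 4x4 one-degree grid at the equator for hand arithmetic."""
    return RasterGrid(n_rows=4, n_cols=4, west=0.0, south=-2.0, east=4.0, north=2.0)


def make_stack(arrays: dict[str, np.ndarray], west=0.0, south=0.0, cell=1.0,
               period="present", source="observed") -> RasterStack:
    """Stack builder for hand-constructed variable grids."""
    first = next(iter(arrays.values()))
    rows, cols = np.asarray(first).shape
    grid = RasterGrid(n_rows=rows, n_cols=cols, west=west, south=south,
                      east=west + cols * cell, north=south + rows * cell)
    return RasterStack(grid=grid, variables={k: np.asarray(v, dtype=float) for k, v in arrays.items()},
                       period_label=period, source_model_label=source)
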