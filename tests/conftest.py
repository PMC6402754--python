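import numpy as np
import pytest

from specyield.spectra import Spectrum, WavelengthGrid
from specyield.synthetic import SyntheticConfig, generate_experiment


@pytest.fixture(scope="session")
def coarse_grid() -> WavelengthGrid:
    """350-2500 nm at 10 nm: cheap but spans all index bands."""
    return WavelengthGrid(350, 2500, 10)


@pytest.fixture(scope="session")
def full_grid() -> WavelengthGrid:
    return WavelengthGrid()


@pytest.fixture(scope="session")
def small_experiment(full_grid):
    """Reference-design synthetic experiment on the canonical 1-nm grid."""
    cfg = SyntheticConfig(grid=full_grid, seed=42)
    dataset, agronomy, wbalance = generate_experiment(cfg)
    return cfg, dataset, agronomy, wbalance


@pytest.fixture(scope="session")
def noiseless_experiment(full_grid):
    cfg = SyntheticConfig(
        grid=full_grid,
        seed=7,
        spectral_noise_sd=0.0,
        agronomic_cv=0.0,
        et_noise_sd_mm=0.0,
    )
    return (cfg, *generate_experiment(cfg))


def random_spectrum(grid: WavelengthGrid, rng: np.random.Generator) -> Spectrum:
    """A strictly positive random spectrum (no special structure)."""
    return Spectrum(grid, rng.uniform(0.01, 0.95, grid.n_bands))
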