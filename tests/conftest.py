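import numpy as np
import pytest

from swirclass.spectra_io import SampleMeta, SpectraDataset, Spectrum, WavelengthGrid


@pytest.fixture
def small_grid() -> WavelengthGrid:
    """A short grid for fast tests: 400-463 nm at 1 nm -> 64 points."""
    return WavelengthGrid(400.0, 463.0, 1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_dataset(grid: WavelengthGrid, n_per_cell: int, rng: np.random.Generator,
                 states=("frozen", "thawed"), classes=(0, 1)) -> SpectraDataset:
    """Random labeled dataset with n_per_cell spectra per (class, state) cell."""
    spectra = []
    for cls in classes:
        for state in states:
            for i in range(n_per_cell):
                r = np.clip(rng.normal(0.5, 0.1, grid.n_points), 0.0, 1.0)
                spectra.append(Spectrum(SampleMeta(f"C{cls}R{i:03d}", cls, state), r))
    return SpectraDataset(grid, spectra)


@pytest.fixture
def small_dataset(small_grid, rng) -> SpectraDataset:
    return make_dataset(small_grid, 10, rng)
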