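import numpy as np
import pytest

from pcdmd import phantom as ph
from pcdmd import simulator as sim
from pcdmd import spectral as sp


@pytest.fixture(scope="session")
def spectrum():
    """Default 140 kV beam with 10 mm Al half-value layer."""
    return sp.build_spectrum(140.0, 10.0)


@pytest.fixture(scope="session")
def mono60():
    """Single-line 60 keV 'spectrum' with a one-bin set, for chord-law oracles."""
    grid = sp.EnergyGrid(np.array([59.0, 60.0, 61.0]), 1.0)
    spec = sp.Spectrum(grid, np.array([0.0, 1.0, 0.0]), 140.0, 1.0)
    return spec, sp.EnergyBinSet(((59.0, 61.0),))


@pytest.fixture(scope="session")
def desk_grid():
    return ph.ImageGrid(64, 250.0 / 64)


@pytest.fixture(scope="session")
def desk_geometry():
    return sim.Geometry.desk(64, 60)


@pytest.fixture(scope="session")
def reference_scan(spectrum, desk_grid, desk_geometry):
    """Noiseless scan of the fixed QA phantom layout (2 Ca + 4 I inserts)."""
    spec = ph.reference_phantom(desk_grid)
    img, lab = sim.simulate_scan(spec, spectrum, geometry=desk_geometry, flux=np.inf)
    return spec, img, lab


@pytest.fixture(scope="session")
def noisy_scan(spectrum, desk_grid, desk_geometry):
    spec = ph.sample_phantom(7, grid=desk_grid)
    img, lab = sim.simulate_scan(spec, spectrum, geometry=desk_geometry, flux=4e5, rng_seed=7)
    return spec, img, lab
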