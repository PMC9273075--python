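import numpy as np
import pytest

from cropspread.calib import CalCurve
from cropspread.synthetic import SyntheticSpec, make_banded_raster, simulate_sites


@pytest.fixture(scope="session")
def identity_curve() -> CalCurve:
    """Calibration curve with mu(t) = t and zero curve error."""
    grid = np.arange(0.0, 10001.0)
    return CalCurve(cal_bp=grid, mu=grid.copy(),
                    sigma_curve=np.zeros_like(grid), name="identity")


@pytest.fixture(scope="session")
def small_spec() -> SyntheticSpec:
    """Desk-tiny synthetic world: 20x40 cells, 4 bands, noiseless."""
    return SyntheticSpec(
        n_rows=20, n_cols=40, cell_size=20.0,
        band_widths=(10, 10, 10, 10), true_speeds=(0.4, 0.8, 1.5, 2.0),
        origin_cell=(10, 0), t0=10000.0, n_sites=24,
        date_noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_spec):
    """(raster, sites) for the tiny noiseless world."""
    raster = make_banded_raster(small_spec)
    sites = simulate_sites(raster, small_spec)
    return raster, sites
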