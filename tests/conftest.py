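import numpy as np
import pytest

from stemheat.forcing import ForcingSeries, synthetic_lab_pulse
from stemheat.grid import StemGeometry, build_grid
from stemheat.properties import SpeciesParams
from stemheat.solver import RunConfig


@pytest.fixture
def lab_geometry():
    """14 cm stem at 2 mm spacing, 8 wedges: small but realistic."""
    return StemGeometry(diameter=0.14, outer_bark_thickness=2e-3,
                        inner_bark_thickness=2e-3, n_wedges=8,
                        radial_spacing=2e-3)


@pytest.fixture
def lab_grid(lab_geometry):
    return build_grid(lab_geometry)


@pytest.fixture
def pine():
    """White-pine-like parameters (moist, light wood)."""
    return SpeciesParams(name="Pinus strobus", dry_wood_density=338.0,
                         dry_bark_density=338.0, max_moisture=1.0,
                         p1=0.63, p2=0.26, p3=0.19, water_loss_rate=0.8)


@pytest.fixture
def maple():
    return SpeciesParams(name="Acer rubrum", dry_wood_density=523.0,
                         dry_bark_density=523.0, max_moisture=0.8063,
                         p1=1.0, p2=0.5, p3=0.2, water_loss_rate=0.8)


@pytest.fixture
def pulse():
    """30 kW/m^2 bench pulse: 60 s ramp, 300 s hold, 600 s cooling."""
    return synthetic_lab_pulse(3e4, 60.0, 300.0, 600.0, ambient=300.0)


@pytest.fixture
def short_config():
    return RunConfig(dt=1.0, total_time=300.0, output_every=30.0,
                     initial_temperature=300.0)


def zero_forcing(t_end=1e5, ambient=300.0):
    return ForcingSeries(np.array([0.0, t_end]), np.zeros((2, 1)), ambient)
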