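import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from flashqa import (DoseGrid, GridGeometry, SimplePlan, default_beam_model,
                     simulate_delivery)
from flashqa._dosecore import gaussian_spot_maps

settings.register_profile(
    "default", derandomize=True, max_examples=60,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def model():
    return default_beam_model()


@pytest.fixture
def small_plan():
    """2x2 spot plan with 10 ms beam-on per spot (1 MU at 100 MU/s)."""
    return SimplePlan(field_id="small", nu=2, nt=2, du=2.5, dt=2.5,
                      mu_per_spot=1.0, intensity=100.0)


@pytest.fixture
def field_plan():
    """10x10 spot field centered on isocenter, UHDR-scale intensity."""
    return SimplePlan(field_id="field", nu=10, nt=10, du=2.5, dt=2.5,
                      u_start=-11.25, t_start=-11.25,
                      mu_per_spot=100.0, intensity=1.0e4)


@pytest.fixture
def clean_delivery(field_plan, model):
    """Noise-free simulated delivery of the 10x10 field."""
    return simulate_delivery(field_plan, model, seed=7)


def make_gaussian_image(geometry: GridGeometry, centers, sigmas, amplitudes,
                        background: float = 0.0) -> DoseGrid:
    """Dose image that is an exact sum of Gaussians (for fit/QA tests)."""
    centers = np.atleast_2d(centers)
    sigmas = np.atleast_2d(sigmas)
    amplitudes = np.atleast_1d(amplitudes)
    # convert peak amplitudes to dose-areas so gaussian_spot_maps peaks match
    dose_area = amplitudes * 2 * np.pi * sigmas[:, 0] * sigmas[:, 1]
    maps = gaussian_spot_maps(geometry, centers, sigmas, dose_area)
    return DoseGrid(geometry, maps.sum(axis=0) + background)


def make_five_spot_image(nominal, sigma=(3.0, 3.0), spacing=1.0,
                         extent=60.0, amplitude=1.0) -> DoseGrid:
    geom = GridGeometry(origin=(-extent, -extent), spacing=spacing,
                        shape=(int(2 * extent / spacing) + 1,
                               int(2 * extent / spacing) + 1))
    n = len(nominal)
    return make_gaussian_image(geom, nominal, [sigma] * n, [amplitude] * n)
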