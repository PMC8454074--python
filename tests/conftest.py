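"""Shared fixtures: small synthetic inputs generated at test time."""

import numpy as np
import pytest

from bbbarray import simdata


def disk_mask(diameter_px: int, shape=None) -> np.ndarray:
    """Filled circular mask of the given diameter (pixel-centre sampling)."""
    r = diameter_px / 2.0
    n = shape or int(diameter_px + 10)
    yy, xx = np.indices((n, n))
    cy = cx = (n - 1) / 2.0
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


@pytest.fixture(scope="session")
def noise_free_config():
    return simdata.SimulationConfig(poisson_gain=0.0, read_noise_sd=0.0, biological_cv=0.0)


@pytest.fixture(scope="session")
def shuttle_params():
    return simdata.default_transport_params("human_shuttle")


@pytest.fixture(scope="session")
def shuttle_condition():
    return simdata.Condition("human_shuttle", "shuttle", dose_nM=100.0, time_min=240.0)


@pytest.fixture(scope="session")
def noise_free_shuttle_stack(noise_free_config, shuttle_params, shuttle_condition):
    """One noise-free rendered shuttle organoid (expensive: session scope)."""
    geometry = noise_free_config.geometry(235.0)
    stack, truth = simdata.render_confocal_stack(
        geometry, shuttle_params, shuttle_condition, noise_free_config, seed=11
    )
    return stack, truth
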