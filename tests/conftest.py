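import numpy as np
import pytest

from nlmopt import NLMSweep, RectROI, simulate_edge_pair
from nlmopt.simulate import SceneSpec, render_scene

PITCH = 0.048
NYQUIST = 1.0 / (2.0 * PITCH)


@pytest.fixture(scope="session")
def edge_scene():
    """Noiseless tilted-edge scene (exact area-fraction rendering)."""
    spec = SceneSpec(kind="edge", fluence=100.0, edge_angle_deg=2.86, edge_contrast=1.0)
    return render_scene(spec, (128, 128), PITCH)


@pytest.fixture(scope="session")
def edge_roi():
    return RectROI(10, 30, 108, 68)


@pytest.fixture(scope="session")
def sim_pair():
    """Standard simulated thin/thick acquisition (fast geometry)."""
    return simulate_edge_pair(shape=(256, 256), seed=1)


@pytest.fixture(scope="session")
def sweep_fit(sim_pair):
    """Fitted 25-step sweep on the standard simulated pair."""
    model = NLMSweep(
        sim_pair.thin,
        sim_pair.thick,
        epi_roi=sim_pair.epi_roi,
        snr_roi=sim_pair.snr_roi,
        n_steps=25,
    )
    return model.fit()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
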