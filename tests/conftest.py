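import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from octdark import PipelineConfig
from octdark import phantom as ph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_grid() -> ph.ScanGrid:
    return ph.ScanGrid(n_bscans=80, n_ascans=80, n_depth=512)


@pytest.fixture(scope="session")
def quiet_phantom(small_grid):
    """Noise-free baseline phantom volume + truth (shared; treat read-only)."""
    vol, truth = ph.render_volume(
        ph.RetinaModel(),
        ph.PhotoresponseKinetics(),
        0.0,
        ph.ExposureField(mode="none"),
        ph.NoiseModel.quiet(),
        small_grid,
    )
    return vol, truth


@pytest.fixture(scope="session")
def speckle_phantom(small_grid):
    """Default-noise baseline phantom volume + truth (shared; treat read-only)."""
    rng = np.random.default_rng(42)
    vol, truth = ph.render_volume(
        ph.RetinaModel(),
        ph.PhotoresponseKinetics(),
        0.0,
        ph.ExposureField(mode="none"),
        ph.NoiseModel(),
        small_grid,
        rng=rng,
    )
    return vol, truth
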