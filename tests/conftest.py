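import numpy as np
import pytest

from capitax import AssayGeometry, GradientModel, SwimmerConfig


@pytest.fixture
def geometry():
    return AssayGeometry(
        origin_px=(120.0, 80.0),
        axis_deg=30.0,
        pixel_scale=2.0,
        frame_rate=30.0,
        control_origin_px=(20.0, 200.0),
        control_axis_deg=-45.0,
    )


@pytest.fixture
def plain_geometry():
    return AssayGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gradient():
    return GradientModel()


def fast_swimmers(**kw):
    """Small, quick swimmer population for simulation tests."""
    defaults = dict(n_cells=30, duration=60.0, dt=1.0 / 30.0, seed=0)
    defaults.update(kw)
    return SwimmerConfig(**defaults)
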