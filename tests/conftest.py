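import numpy as np
import pytest

from myotrack import PhantomSpec, build_phantom
from myotrack.core import ScalarVolume, VolumeGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_voxel_geometry():
    return VolumeGeometry.from_params((1.5, 1.5, 6.0), (1, 1, 1))


@pytest.fixture(scope="session")
def default_phantom():
    """One subject with the default two-session conditions (seed 3)."""
    return build_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def water_images(default_phantom):
    """Session water magnitude images M0*(1-FF) for registration tests."""
    out = {}
    for t in ("A", "B"):
        truth = default_phantom
        fg = truth.labels[t].labels > 0
        vals = np.where(fg, 100.0 * (1 - truth.maps[t]["ff"].values), 0.0)
        out[t] = ScalarVolume(truth.geometry[t], vals)
    return out


@pytest.fixture(scope="session")
def session_transform(water_images):
    """Registration of the default phantom's sessions (shared: it is slow)."""
    from myotrack.align import register_sessions

    return register_sessions(water_images["A"], water_images["B"])
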