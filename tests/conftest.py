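import numpy as np
import pytest
from hypothesis import settings

from natsc.phantom import PhantomGeometry, PhantomTruth, generate_phantom

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def coarse_truth():
    """3 mm hi-res phantom: fast enough for per-test use, same world geometry."""
    return PhantomTruth(hi_res_voxel_mm=(3.0, 3.0, 3.0), seed=0)


@pytest.fixture(scope="session")
def coarse_phantom(geometry, coarse_truth):
    return generate_phantom(geometry, coarse_truth)


@pytest.fixture(scope="session")
def fine_sim():
    """2 mm hi-res noiseless imaging chain shared across recovery tests."""
    from natsc.pipeline import ImagingSimulator

    return ImagingSimulator(
        PhantomGeometry(), PhantomTruth(hi_res_voxel_mm=(2.0, 2.0, 2.0)), 0.0
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
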