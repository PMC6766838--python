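import numpy as np
import pytest

from ricelodging import BandImage, BinaryMask, SceneSpec, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def rgb_image(rng):
    px = rng.integers(0, 256, size=(24, 32, 3), dtype=np.uint8)
    return BandImage(px, ("R", "G", "B"), "8bit")


@pytest.fixture
def rgn_image(rng):
    px = rng.integers(0, 256, size=(24, 32, 3), dtype=np.uint8)
    return BandImage(px, ("R", "G", "NIR"), "8bit")


@pytest.fixture
def checkerboard_mask():
    rr, cc = np.mgrid[0:16, 0:16]
    return BinaryMask(((rr + cc) % 2).astype(np.uint8))


@pytest.fixture(scope="session")
def small_scene():
    """A 192x256 scene with ~30% lodged area, shared across tests."""
    spec = SceneSpec(height=192, width=256, target_lodged_fraction=0.3,
                     n_blobs=3, seed=7)
    return generate_scene(spec, "rgb")
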