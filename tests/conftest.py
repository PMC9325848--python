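import numpy as np
import pytest

import corneastain as cs

DATA_DIR = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def small_scene_factory():
    """Scenes on a reduced 320x320 canvas: fast unit-test renders."""

    def make(n_spots, seed=1, noise_sigma=0.0, with_artifacts=False):
        base = cs.SceneSpec(
            shape=(320, 320), cornea_center=(160.0, 160.0),
            cornea_axes=(168.0, 152.0), roi_axes=(144.0, 130.0),
            pupil_radius=32.0, highlight=(160.0, 100.0, 14.0, 320.0),
            seed=seed, noise_sigma=noise_sigma)
        return cs.random_scene(n_spots, seed=seed, noise_sigma=noise_sigma,
                               with_artifacts=with_artifacts, base=base)

    return make


@pytest.fixture(scope="session")
def rendered_small(small_scene_factory):
    """One rendered 10-spot noise-free small image with its ROI and truth."""
    scene = small_scene_factory(10, seed=3)
    return cs.generate_cornea_image(scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
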