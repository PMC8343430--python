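import numpy as np
import pytest

from snap.synthetic import SceneParams, generate_scene, generate_scenes


@pytest.fixture(scope="session")
def small_scene_params():
    """Desk-scale scene parameters used across the suite (144x192 canvas)."""
    return SceneParams.for_canvas(
        144, 192, nodule_count_mean=8.0, nodule_count_dispersion=4.0,
        n_laterals=4, n_distractors=1, seed=42)


@pytest.fixture(scope="session")
def small_scene(small_scene_params):
    return generate_scene(small_scene_params)


@pytest.fixture(scope="session")
def scene_batch(small_scene_params):
    """Ten deterministic small scenes."""
    return generate_scenes(10, small_scene_params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
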