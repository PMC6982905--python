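import numpy as np
import pytest

from rodtrack import ArenaScene, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_scene(**kwargs):
    """A fast-to-render arena for unit tests; benchmarks set sizes explicitly."""
    defaults = dict(width=320, height=240, n_animals=1, n_frames=3, noise_sigma=0.0, seed=0)
    defaults.update(kwargs)
    return ArenaScene(**defaults)


@pytest.fixture
def single_animal_frame():
    """One noiseless frame with one dark ellipse, plus its truth row."""
    scene = small_scene(initial_states=[(160.0, 120.0, 5.0, 0.0)])
    frames, truth = generate_scene(scene)
    return next(frames), truth[truth["frame"] == 0].iloc[0], scene
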