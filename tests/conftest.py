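import numpy as np
import pytest

from endostitch.synthetic import SceneSpec, generate_pair, translation_homography


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def texture():
    """A high-contrast band-limited texture with plenty of keypoints."""
    from endostitch.synthetic import value_noise

    g = np.random.default_rng(7)
    t = value_noise((128, 128), 5, 0.85, g)
    return 1.0 / (1.0 + np.exp(-8.0 * (t - 0.5)))


@pytest.fixture(scope="session")
def translated_pair():
    """Noise- and jitter-free pair under a pure 40 px translation."""
    spec = SceneSpec(seed=3, gain_jitter=0.0, offset_jitter=0.0, noise_std=0.0)
    return generate_pair(spec, translation_homography(40.0, 5.0))


@pytest.fixture(scope="session")
def detected(texture):
    """Keypoints + scale space of the session texture."""
    from endostitch import scalespace

    kps, ss = scalespace.detect_keypoints(texture)
    assert len(kps) > 20
    return kps, ss
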