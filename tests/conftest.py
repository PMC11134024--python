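import numpy as np
import pytest

from gazetune.synthetic import generate_gaze


@pytest.fixture(scope="session")
def small_gaze():
    """A short labeled recording exercising all three event classes."""
    return generate_gaze(n_events=12, rate_hz=500.0, noise_sd=0.05, seed=7)


@pytest.fixture(scope="session")
def blob_data():
    """Three well-separated Gaussian blobs with known means."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    X = np.vstack([rng.normal(c, 0.01, size=(30, 2)) for c in centers])
    labels = np.repeat([0, 1, 2], 30)
    return X, labels, centers
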