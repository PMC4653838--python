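import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_views(rng):
    """Two small aligned data types with a weak planted bipartition."""
    ids = [f"P{i}" for i in range(12)]
    shift = np.repeat([0.0, 1.5], 6)[:, None]
    v1 = pd.DataFrame(rng.normal(size=(12, 8)) + shift, index=ids)
    v2 = pd.DataFrame(rng.normal(size=(12, 5)) + shift, index=ids)
    return [v1, v2]


@pytest.fixture
def blob_features(rng):
    """Three well-separated Gaussian blobs (30 patients, 5 features)."""
    centers = np.array([[0.0] * 5, [8.0] * 5, [-8.0] * 5])
    labels = np.repeat([0, 1, 2], 10)
    X = centers[labels] + rng.normal(scale=0.5, size=(30, 5))
    return X, labels
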