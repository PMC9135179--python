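import numpy as np
import pytest

from swarmeeg.synthetic import (generate_bonn_like, pool_segments,
                                segment_recording)


@pytest.fixture(scope="session")
def small_segments():
    """4 recordings per class -> 184 labelled segments of length 178."""
    recs = generate_bonn_like(4, seed=11)
    return pool_segments([segment_recording(r) for r in recs])


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable 2-D features, 120 samples."""
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 120)
    X = rng.standard_normal((120, 2)) * 0.3 + (2 * y[:, None] - 1)
    return X, y
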