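import numpy as np
import pytest

from latmap.matrices import FeatureMatrix
from latmap import agreement


@pytest.fixture
def planted_map():
    """A (20x5, seed 11), W (5x3, seed 12), B = A W exactly."""
    rng_a = np.random.default_rng(11)
    rng_w = np.random.default_rng(12)
    A = rng_a.normal(size=(20, 5))
    W = rng_w.normal(size=(5, 3))
    B = A @ W
    ids = [f"s{i}" for i in range(20)]
    return {
        "A": FeatureMatrix(A, sample_ids=ids, source="latent"),
        "B": FeatureMatrix(B, sample_ids=ids, source="expert"),
        "W": W,
    }


@pytest.fixture
def worked_2x2():
    """The hand-evaluated binary table: TP=40, FN=10, FP=5, TN=45."""
    r1 = ["pos"] * 50 + ["neg"] * 50
    r2 = ["pos"] * 40 + ["neg"] * 10 + ["pos"] * 5 + ["neg"] * 45
    return agreement.confusion(r1, r2)
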