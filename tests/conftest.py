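import numpy as np
import pytest

from swarmfs.data_io import FeatureMatrix


def make_matrix(values, labels, feature_ids=None, sample_ids=None, missing=None):
    values = np.asarray(values, dtype=float)
    n, d = values.shape
    return FeatureMatrix(
        values=values,
        labels=np.asarray(labels, dtype=object),
        feature_ids=np.asarray(
            feature_ids if feature_ids is not None else [f"f{i}" for i in range(d)],
            dtype=object,
        ),
        sample_ids=np.asarray(
            sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)],
            dtype=object,
        ),
        missing_mask=missing,
    )


@pytest.fixture
def two_cluster_matrix():
    """20 samples, 3 features; only feature 0 separates the classes."""
    rng = np.random.default_rng(7)
    a = rng.normal(0.0, 0.5, size=(10, 3))
    b = rng.normal(0.0, 0.5, size=(10, 3))
    a[:, 0] -= 5.0
    b[:, 0] += 5.0
    values = np.vstack([a, b])
    labels = ["neg"] * 10 + ["pos"] * 10
    return make_matrix(values, labels)


@pytest.fixture
def separable_matrix():
    """Two well-separated classes on every feature (fully separable)."""
    rng = np.random.default_rng(12)
    a = rng.normal(-4.0, 0.3, size=(12, 4))
    b = rng.normal(4.0, 0.3, size=(12, 4))
    return make_matrix(np.vstack([a, b]), ["neg"] * 12 + ["pos"] * 12)
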