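import numpy as np
import pytest

from sonoliver import (
    CIRRHOTIC_SPEC,
    NORMAL_SPEC,
    ClusteringConfig,
    extract_features,
    generate_image,
)


@pytest.fixture(scope="session")
def two_blob_1d():
    """Two well-separated 1-D intensity blobs plus labels of the blob id."""
    rng = np.random.default_rng(42)
    a = rng.normal(0.2, 0.02, 40)
    b = rng.normal(0.8, 0.02, 40)
    return np.concatenate([a, b]), np.r_[np.zeros(40, int), np.ones(40, int)]


@pytest.fixture(scope="session")
def separable_features():
    """Bayes-separable 2-D feature set: two tight Gaussian classes."""
    rng = np.random.default_rng(7)
    x0 = rng.normal([0.2, 0.3], 0.03, size=(60, 2))
    x1 = rng.normal([0.7, 0.8], 0.03, size=(60, 2))
    X = np.vstack([x0, x1])
    y = np.r_[np.zeros(60, int), np.ones(60, int)]
    return X, y


@pytest.fixture(scope="session")
def small_image_batch():
    """20 normal + 20 cirrhotic 64x64 synthetic images with labels."""
    imgs, labels = [], []
    for i in range(20):
        imgs.append(generate_image(NORMAL_SPEC, 64, 64, seed=100 + i))
        labels.append(0)
    for i in range(20):
        imgs.append(generate_image(CIRRHOTIC_SPEC, 64, 64, seed=200 + i))
        labels.append(1)
    return imgs, labels


@pytest.fixture(scope="session")
def fcm_feature_table(small_image_batch):
    """Raw FCM feature matrix extracted from the small image batch."""
    imgs, labels = small_image_batch
    cfg = ClusteringConfig(c=3, seed=5)
    X = np.vstack([extract_features(im, "fcm", cfg).values for im in imgs])
    return X, np.asarray(labels)
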