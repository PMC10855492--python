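import numpy as np
import pytest

from gbsd import nn
from gbsd.synthetic import SyntheticConfig, generate_lesion_image


@pytest.fixture(scope="session")
def clean_cfg() -> SyntheticConfig:
    """Generator config with hair and sensor noise disabled."""
    return SyntheticConfig(hair_strokes=0, noise_sigma=0.0, seed=3)


@pytest.fixture(scope="session")
def benign_record(clean_cfg):
    return generate_lesion_image("benign", clean_cfg, seed=7)


@pytest.fixture(scope="session")
def malignant_record(clean_cfg):
    return generate_lesion_image("malignant", clean_cfg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_toy_net(rng: np.random.Generator, cin: int = 1, size: int = 8) -> nn.Sequential:
    """Small conv->ReLU->pool->dense->ReLU->dense classifier for grad tests."""
    return nn.Sequential(
        [
            nn.Conv2d(cin, 4, 3, rng),
            nn.ReLU(),
            nn.MaxPool2d(2),
            nn.Flatten(),
            nn.Dense(4 * (size // 2) ** 2, 6, rng),
            nn.ReLU(),
            nn.Dense(6, 2, rng),
        ]
    ).astype(np.float64)


@pytest.fixture()
def toy_net(rng):
    return make_toy_net(rng)


def separable_stacks(n_per_class: int, channels: int = 2, size: int = 32, seed: int = 0):
    """Tiny synthetic feature stacks with a linearly separable class signal."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            base = rng.normal(0.5, 0.1, size=(channels, size, size))
            if label == 1:
                yy, xx = np.mgrid[0:size, 0:size]
                blob = np.exp(-((yy - size / 2) ** 2 + (xx - size / 2) ** 2) / (size / 3) ** 2)
                base += 0.8 * blob[None]
            X.append(np.clip(base, 0, 2))
            y.append(label)
    order = np.random.default_rng(seed + 1).permutation(len(X))
    return np.asarray(X, dtype=np.float32)[order], np.asarray(y, dtype=np.int64)[order]
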