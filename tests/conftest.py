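import numpy as np
import pytest

from fundusseg.network import NetworkConfig
from fundusseg.phantom import generate_dataset


class ChannelProbNet:
    """Stub segmentation net: the probability map is the image's first
    channel (scaled to [0,1]).  Lets tests dictate per-sample losses."""

    def __init__(self, input_side):
        self.config = NetworkConfig(input_side=max(16, (input_side // 16) * 16))
        self._side = input_side

    def forward_batch(self, x, train=False):
        return np.ascontiguousarray(x[..., 0:1]).astype(np.float64)

    def predict(self, image):
        img = np.asarray(image)
        if np.issubdtype(img.dtype, np.integer):
            return img[..., 0].astype(np.float64) / 255.0
        return img[..., 0].astype(np.float64)


class ConstantNet:
    """Stub net that predicts a constant probability everywhere."""

    def __init__(self, value, input_side=64):
        self.value = value
        self.config = NetworkConfig(input_side=input_side)

    def forward_batch(self, x, train=False):
        return np.full(x.shape[:3] + (1,), self.value, dtype=np.float64)

    def predict(self, image):
        return np.full(np.asarray(image).shape[:2], self.value, dtype=np.float64)


@pytest.fixture(scope="session")
def phantom_population():
    """A small deterministic phantom population shared across tests."""
    return generate_dataset(24, 0.2, side=64, seed=42)


@pytest.fixture
def channel_net_factory():
    return ChannelProbNet


@pytest.fixture
def constant_net_factory():
    return ConstantNet
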