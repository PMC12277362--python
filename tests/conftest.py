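import numpy as np
import pytest

from vusmamba.config import ModelConfig, RunConfig, SSLConfig, TrainConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_model_config():
    """Smallest config exercising all four encoder stages."""
    return ModelConfig(base_channels=8, state_size=4)


@pytest.fixture
def micro_model_config():
    """Two-stage config for fast layer-level tests (divisor 8)."""
    return ModelConfig(base_channels=4, state_size=2,
                       encoder_depths=(1, 1), decoder_depths=(1,))


def numeric_gradient(f, arrays, eps=1e-6):
    """Central-difference gradients of scalar f(list of arrays)."""
    grads = []
    for a in arrays:
        g = np.zeros_like(a)
        it = np.nditer(a, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = a[idx]
            a[idx] = orig + eps
            fp = f(arrays)
            a[idx] = orig - eps
            fm = f(arrays)
            a[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
        grads.append(g)
    return grads
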