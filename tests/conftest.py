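import numpy as np
import pytest

from biossl.model_core import LayerSpec, Network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_net():
    """Small conv/pool/conv/flatten/linear network in float64 for oracles."""
    specs = [
        LayerSpec("conv", activation="none", channels_out=4, kernel=3),
        LayerSpec("maxpool", activation="tanh", pool_size=2),
        LayerSpec("conv", activation="hardtanh", channels_out=6, kernel=3),
        LayerSpec("flatten"),
        LayerSpec("linear", channels_out=5),
    ]
    return Network(specs, (2, 8, 8), seed=7, dtype=np.float64)


@pytest.fixture
def tiny_dataset():
    from biossl.synthetic import SyntheticDatasetSpec, generate

    return generate(SyntheticDatasetSpec(images_per_class=40, seed=5))


def finite_difference(f, arr, indices, eps=1e-6):
    """Central differences of scalar ``f`` w.r.t. entries of ``arr``."""
    out = {}
    for idx in indices:
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f()
        arr[idx] = orig - eps
        fm = f()
        arr[idx] = orig
        out[idx] = (fp - fm) / (2 * eps)
    return out
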