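import numpy as np
import pytest

from icnet.data_io import batch_generator, extract_slices
from icnet.synthetic import PhantomSpec, make_tumor_phantom


@pytest.fixture(scope="session")
def phantom():
    """One noiseless-ish multimodal phantom subject, shared across tests."""
    return make_tumor_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def phantom_slices(phantom):
    """Preprocessed 64x64 axial slices (FLAIR + T1ce channels)."""
    return extract_slices(phantom, target_size=(64, 64), modalities=("flair", "t1ce"))


@pytest.fixture(scope="session")
def center_slice(phantom_slices):
    """The mid-tumor slice, used for overfit smoke training."""
    return phantom_slices[len(phantom_slices) // 2]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def brute_force_conv(x, weights):
    """Quadruple-loop direct-summation convolution oracle (valid padding)."""
    b, h, w, cin = x.shape
    fh, fw, _, cout = weights.shape
    oh, ow = h - fh + 1, w - fw + 1
    out = np.zeros((b, oh, ow, cout))
    for n in range(b):
        for i in range(oh):
            for j in range(ow):
                for o in range(cout):
                    out[n, i, j, o] = np.sum(x[n, i:i + fh, j:j + fw, :] * weights[..., o])
    return out
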