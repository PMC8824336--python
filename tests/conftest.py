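import numpy as np
import pytest

from frugalseg.synthetic import SynthConfig, generate_arrays


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small in-memory synthetic dataset shared across tests."""
    cfg = SynthConfig(n_samples=24, image_size=32, seed=7)
    return generate_arrays(cfg)


def random_sample(rng, h, w, C):
    """Random binary ground truth, simplex prediction and mask vector."""
    gt = (rng.random((h, w, C)) > 0.6).astype(float)
    logits = rng.normal(size=(h, w, C))
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    pred = e / e.sum(axis=-1, keepdims=True)
    m = (rng.random(C) > 0.4).astype(float)
    if m.sum() == 0:
        m[rng.integers(C)] = 1.0
    return gt, pred, m
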