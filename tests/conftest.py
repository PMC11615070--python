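import numpy as np
import pytest

from neurofuse.benchmarks import REDUCED_MEG_SHAPE, REDUCED_MRI_SHAPE
from neurofuse.synthetic import default_effect, generate_paired_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_dataset():
    """12 + 12 subjects at reduced shapes with strong effects in both
    modalities; shared across training-related tests."""
    effect = default_effect(REDUCED_MRI_SHAPE, box_size=8, mri_effect_d=2.0,
                            meg_power_ratio=3.0)
    return generate_paired_dataset(12, 12, seed=42,
                                   meg_shape=REDUCED_MEG_SHAPE,
                                   mri_shape=REDUCED_MRI_SHAPE, effect=effect)


def numeric_gradient(f, x, eps=1e-3):
    """Central finite differences of a scalar function w.r.t. array x."""
    g = np.zeros(x.shape, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f()
        x[idx] = orig - eps
        fm = f()
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
    return g
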