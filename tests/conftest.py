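import numpy as np
import pytest

import raterseg as rs


@pytest.fixture(scope="session")
def small_samples():
    """Twenty 32x32 binary shapes for fast structural tests."""
    return rs.generate_shapes(20, 32, 32, num_classes=2, seed=42)


@pytest.fixture(scope="session")
def one_sample(small_samples):
    return small_samples[0]


@pytest.fixture(scope="session")
def panel_stack(one_sample):
    return rs.build_default_panel(one_sample.gt_mask, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_soft_label(rng, h=8, w=8, c=2):
    p = rng.dirichlet(np.ones(c), size=(h, w))
    return rs.SoftLabel(p)
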