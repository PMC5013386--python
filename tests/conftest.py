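import numpy as np
import pytest

from biofilmquant.features import FeatureConfig, compute_feature_stack
from biofilmquant.preprocess import PreprocessConfig, apply_preset
from biofilmquant.synthgen import SyntheticSpec, render_pair


@pytest.fixture(scope="session")
def sla_pair():
    """Canonical SLA-like before/after pair (256x256, 30% coverage)."""
    return render_pair(SyntheticSpec(surface_type="sla", width=256, height=256, seed=0))


@pytest.fixture(scope="session")
def polished_pair():
    """Canonical polished before/after pair (256x256, 30% coverage)."""
    return render_pair(SyntheticSpec(surface_type="polished", width=256, height=256, seed=0))


@pytest.fixture(scope="session")
def sla_stack(sla_pair):
    """Default feature stack of the preprocessed canonical SLA before frame."""
    img = apply_preset(sla_pair.before_img, PreprocessConfig.for_surface("sla"))
    return compute_feature_stack(img, FeatureConfig.default())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
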