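import numpy as np
import pytest
from hypothesis import settings

from pflyolo import synthetic as syn

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small multi-class labelled set used across datakit/eval tests."""
    cfg = syn.SynthConfig(n_classes=4, per_class=3, image_size=48, seed=7)
    return syn.gen_face_dataset(cfg)
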