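import numpy as np
import pytest

from gaitseg import SynthParams, synth_walk
from gaitseg.template_annotate import load_model_stride


@pytest.fixture(scope="session")
def healthy_walk():
    """One healthy-morphology synthetic walk, fixed seed."""
    return synth_walk(SynthParams(seed=7))


@pytest.fixture(scope="session")
def model():
    """Packaged synthetic model stride."""
    return load_model_stride()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
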