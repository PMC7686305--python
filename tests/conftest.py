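import numpy as np
import pytest

from qrelax.sequence_models import make_default_flip_train, protocol_presets
from qrelax.types import MRFSequenceParams


@pytest.fixture(scope="session")
def presets():
    return protocol_presets()


@pytest.fixture(scope="session")
def mrf_seq(presets) -> MRFSequenceParams:
    """The full 979-excitation default fingerprinting train."""
    return presets["mrf_default"]


@pytest.fixture(scope="session")
def short_seq() -> MRFSequenceParams:
    """A 240-excitation train for tests where the full train is overkill."""
    return MRFSequenceParams(
        flip_angles_deg=tuple(make_default_flip_train(n=240)),
        tr_ms=10.0, te_ms=2.5, inversion=True,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
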