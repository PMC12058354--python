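import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swabdiv.io import Read

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_read(seq: str, q: int = 20, rid: str = "r1", sample: str = "s1") -> Read:
    return Read(rid, seq, tuple([q] * len(seq)), sample)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def read_factory():
    return make_read
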