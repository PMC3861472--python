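import numpy as np
import pytest
from hypothesis import settings

from supersage.tagging import ANCHOR, TAG_LENGTH

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_tag(rng) -> str:
    tail = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=TAG_LENGTH - 4)])
    return ANCHOR + tail


@pytest.fixture
def make_tags(rng):
    def _make(n: int) -> list[str]:
        return [random_tag(rng) for _ in range(n)]

    return _make
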