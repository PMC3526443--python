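import numpy as np
import pytest

from bpmedian import MedianInstance, uniform_random_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


def random_instance(n, k, signed, rng):
    return MedianInstance([uniform_random_genome(n, signed, rng) for _ in range(k)])
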