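import numpy as np
import pytest

from dpmtp import PValueFamily


@pytest.fixture
def rng():
    return np.random.default_rng(20250924)


def random_families(n, m, seed):
    """n i.i.d. uniform p-value families of size m (shared test helper)."""
    gen = np.random.default_rng(seed)
    return [PValueFamily(gen.random(m)) for _ in range(n)]
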