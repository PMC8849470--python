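import numpy as np
import pytest

from semrsa.rdm import PatternSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_pattern_set(seed, n_runs=4, n_conditions=3, n_channels=5):
    rng = np.random.default_rng(seed)
    labels = tuple(f"w{i:02d}" for i in range(n_conditions))
    return PatternSet(
        rng.standard_normal((n_runs, n_conditions, n_channels)), labels
    )
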