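import numpy as np
import pytest

from blocksurv import (
    BlockedDataset,
    BlockStructure,
    SurvivalOutcome,
    make_multiomics_fixture,
)


@pytest.fixture(scope="session")
def tiny_data() -> BlockedDataset:
    """Five-block multi-omics-shaped data set, n=60, p=200."""
    return make_multiomics_fixture("tiny", seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_survival(rng, n, censor_frac=0.3, tie_prob=0.0):
    """Small random survival sample with optional tied times."""
    if tie_prob > 0:
        time = rng.integers(1, max(2, n // 2), size=n).astype(float)
    else:
        time = rng.exponential(1.0, size=n) + 0.01
    status = (rng.uniform(size=n) > censor_frac).astype(int)
    return time, status


@pytest.fixture(scope="session")
def two_block_signal_data() -> BlockedDataset:
    """Strong signal confined to block 1; block 2 is pure noise."""
    from blocksurv import SimSpec, simulate_blocked_survival

    spec = SimSpec(
        n=150,
        block_sizes=(50, 200),
        n_informative=(10, 0),
        beta=(1.0, 0.0),
        censoring=0.3,
        seed=11,
    )
    return simulate_blocked_survival(spec)
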