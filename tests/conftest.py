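import numpy as np
import pandas as pd
import pytest

from gutnet.io import ReadCountTable
from gutnet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-condition synthetic dataset, shared across tests."""
    return generate_dataset(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def synthetic_strong():
    """Strong planted signal for recovery tests."""
    return generate_dataset(SyntheticConfig.planted_recovery(seed=5))


@pytest.fixture()
def tiny_table():
    return ReadCountTable(
        pd.DataFrame(
            [[5, 0, 2], [1, 3, 4]], index=["s1", "s2"], columns=["ga", "gb", "gc"]
        )
    )


def random_count_table(rng: np.random.Generator, n=4, p=6, depth=200) -> ReadCountTable:
    probs = rng.dirichlet(np.ones(p), size=n)
    counts = np.vstack([rng.multinomial(depth, pr) for pr in probs])
    return ReadCountTable(
        pd.DataFrame(
            counts,
            index=[f"s{i}" for i in range(n)],
            columns=[f"g{j}" for j in range(p)],
        )
    )
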