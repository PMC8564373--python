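import itertools

import numpy as np
import pandas as pd
import pytest

from bitbow.frequency import CodeDistribution, build_code_distribution


@pytest.fixture
def uniform5() -> CodeDistribution:
    """Uniform distribution over the 31 nonzero 5-bit codes."""
    return build_code_distribution(np.full(5, 0.5))


@pytest.fixture
def skewed5() -> CodeDistribution:
    """A biased 5-bit distribution (unequal module frequencies)."""
    return build_code_distribution(np.array([0.4, 0.22, 0.55, 0.21, 0.32]))


@pytest.fixture
def tiny_clusters() -> pd.DataFrame:
    """One brain with codes [X, X, Y, Z]: 50% of clusters share a code."""
    return pd.DataFrame(
        {
            "brain_id": ["b1"] * 4,
            "cluster_id": [f"c{i}" for i in range(4)],
            "code": ["10000", "10000", "01000", "00100"],
        }
    )


def brute_force_collision_rate(probs: np.ndarray, n: int) -> float:
    """Exact E[(draws - distinct)/draws] by full enumeration of n-tuples."""
    probs = np.asarray(probs, dtype=float)
    total = 0.0
    for tup in itertools.product(range(probs.size), repeat=n):
        total += np.prod(probs[list(tup)]) * (n - len(set(tup)))
    return total / n
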