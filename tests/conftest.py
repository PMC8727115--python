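import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from ndcrfs import Dataset
from ndcrfs.info_theory import DiscreteColumn

# canonical 8-sample fixture used across modules:
#   f1 = noisy copy of the class, f2 = exact duplicate of f1,
#   f3 = class-balanced (zero MI with the class)
TOY_A = {
    "f1": [0, 0, 0, 1, 0, 1, 1, 1],
    "f2": [0, 0, 0, 1, 0, 1, 1, 1],
    "f3": [0, 1, 0, 1, 0, 1, 0, 1],
    "class": [0, 0, 0, 0, 1, 1, 1, 1],
}


@pytest.fixture
def toy_a() -> Dataset:
    return Dataset(pd.DataFrame(TOY_A))


@pytest.fixture
def xor_triple():
    """X, Y iid balanced bits, C = X xor Y, all four patterns equally frequent."""
    x = DiscreteColumn.from_values([0, 0, 1, 1])
    y = DiscreteColumn.from_values([0, 1, 0, 1])
    c = DiscreteColumn.from_values([0, 1, 1, 0])
    return x, y, c


@pytest.fixture
def xor_dataset():
    """X, Y, C = X xor Y plus an independent balanced noise bit, as a Dataset.

    Built on the replicated 4-pattern grid so all empirical distributions are
    exact (noise z cycles through both values within each pattern)."""
    x = np.tile([0, 0, 1, 1], 4)
    y = np.tile([0, 1, 0, 1], 4)
    z = np.repeat([0, 1], 8)
    frame = pd.DataFrame({"x": x, "y": y, "z": z, "class": (x + y) % 2})
    return Dataset(frame)


def random_columns(rng: np.random.Generator, k: int = 3, max_n: int = 30, max_arity: int = 4):
    """k random equal-length discrete columns (each arity >= 2)."""
    n = int(rng.integers(2, max_n + 1))
    cols = []
    for _ in range(k):
        arity = int(rng.integers(2, max_arity + 1))
        cols.append(DiscreteColumn(rng.integers(0, arity, n), arity))
    return cols


def random_dataset(rng: np.random.Generator, n_samples: int = 40, n_features: int = 6) -> Dataset:
    cols = {
        f"f{i}": rng.integers(0, int(rng.integers(2, 4)), n_samples)
        for i in range(n_features)
    }
    cols["class"] = rng.integers(0, 2, n_samples)
    return Dataset(pd.DataFrame(cols))
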