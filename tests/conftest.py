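import numpy as np
import pytest

from rumselect.data_model import DecisionTable
from rumselect.synthetic import fixture_example1, fixture_example2


@pytest.fixture
def example1_vectors():
    return fixture_example1()


@pytest.fixture
def example2():
    """(SimilarityMatrix, labels) of the five-sample desk example."""
    return fixture_example2()


def random_table(rng: np.random.Generator, n: int, m: int, n_classes: int = 2) -> DecisionTable:
    """A random normalized decision table with every class represented."""
    values = rng.uniform(0.0, 1.0, size=(n, m))
    while True:
        codes = rng.integers(0, n_classes, size=n)
        if len(np.unique(codes)) == n_classes:
            break
    labels = np.array([f"c{c}" for c in codes], dtype=object)
    return DecisionTable(
        values=values,
        labels=labels,
        attribute_ids=[f"a{j}" for j in range(m)],
        class_ids=[f"c{c}" for c in sorted(set(codes))],
        normalized=True,
    )


@pytest.fixture
def make_random_table():
    return random_table
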