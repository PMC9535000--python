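import numpy as np
import pytest

from pelnet.io_formats import AbundanceTable, to_relative
from pelnet.synthetic import SyntheticDesign, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset shared across tests."""
    return generate_dataset(seed=1)


@pytest.fixture()
def small_table():
    values = np.array([[4.0, 1.0, 0.0],
                       [2.0, 1.0, 3.0],
                       [2.0, 2.0, 1.0]])
    return AbundanceTable(["A", "B", "C"], ["s1", "s2", "s3"], values)


@pytest.fixture()
def rel_table(small_table):
    return to_relative(small_table)
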