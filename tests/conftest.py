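import numpy as np
import pytest

from refstab.ct_data import CtMatrix
from refstab.synthetic import default_design, simulate_ct


@pytest.fixture
def toy_abc() -> CtMatrix:
    """3-gene toy: B = A + 1 (perfectly correlated pair), C more variable."""
    a = np.array([20.0, 21.0, 22.0, 23.0])
    c = np.array([20.0, 20.0, 24.0, 24.0])
    return CtMatrix(np.column_stack([a, a + 1.0, c]), ["s1", "s2", "s3", "s4"], ["A", "B", "C"])


@pytest.fixture
def random_matrix() -> CtMatrix:
    rng = np.random.default_rng(42)
    vals = rng.uniform(15.0, 35.0, size=(12, 5))
    return CtMatrix(vals, [f"s{i}" for i in range(12)], [f"g{j}" for j in range(5)])


@pytest.fixture(scope="session")
def default_dataset():
    """One draw from the study-default synthetic design."""
    return simulate_ct(default_design(), seed=7)
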