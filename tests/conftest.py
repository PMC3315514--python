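import numpy as np
import pytest

from coref import ReferenceSet, TestPair


@pytest.fixture
def five_sample_fixture():
    """Tiny hand-checkable dataset: N=5 samples, k=3 reference columns.

    The correlation profile of x1 against (y_a, y_b, y_c) is (0.8, -1.0, 0.8)
    by the textbook Pearson formula.
    """
    x1 = np.array([1.0, 2, 3, 4, 5])
    x2 = np.array([2.0, 1, 3, 5, 4])
    Y = ReferenceSet(
        y=np.column_stack(
            [
                [2.0, 1, 4, 3, 5],
                [5.0, 4, 3, 2, 1],
                [1.0, 3, 2, 5, 4],
            ]
        ),
        labels=("y_a", "y_b", "y_c"),
    )
    return TestPair(x1=x1, x2=x2), Y


@pytest.fixture
def gaussian_dataset():
    """A moderately sized random dataset with no built-in structure."""
    rng = np.random.default_rng(1234)
    n, k = 40, 12
    pair = TestPair(x1=rng.standard_normal(n), x2=rng.standard_normal(n))
    Y = ReferenceSet(y=rng.standard_normal((n, k)))
    return pair, Y
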