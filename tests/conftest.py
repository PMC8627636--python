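import numpy as np
import pytest

from mapsogs.data import ExpressionDataset
from mapsogs.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def tiny_dataset() -> ExpressionDataset:
    """Two classes of two samples, two genes, one of them discriminative."""
    values = np.array([[0.0, 5.0], [2.0, 4.9], [4.0, 5.1], [6.0, 5.0]])
    return ExpressionDataset(values, ("G1", "G2"), ("A", "A", "B", "B"))


@pytest.fixture
def synthetic_pair():
    """Default synthetic benchmark dataset plus its ground truth (seed 0)."""
    return generate_dataset(SyntheticSpec(seed=0))


@pytest.fixture
def separable_dataset() -> ExpressionDataset:
    """Linearly separable one-informative-gene dataset, 6 per class."""
    rng = np.random.default_rng(7)
    n = 12
    labels = tuple("A" if i < 6 else "B" for i in range(n))
    informative = np.array([0.0] * 6 + [10.0] * 6) + rng.normal(0, 0.1, n)
    noise = rng.normal(0, 1, n)
    return ExpressionDataset(
        np.column_stack([informative, noise]), ("G1", "G2"), labels
    )
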