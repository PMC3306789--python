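import numpy as np
import pytest

from predex import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_dataset():
    """Three genes, 2 control + 2 treatment replicates, hand-sized values."""
    return ExpressionDataset(
        gene_ids=["gA", "gB", "gC"],
        control=np.array([[1.0, 1.0], [0.0, 2.0], [-1.0, 1.0]]),
        treatment=np.array([[2.0, 4.0], [0.0, 2.0], [3.0, 5.0]]),
    )
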