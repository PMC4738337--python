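import numpy as np
import pandas as pd
import pytest

from orthoclust import ExpressionMatrix


def make_matrix(values, genes=None, samples=None, species="test"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{j + 1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), species)


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(42)
    return make_matrix(rng.normal(6, 1, size=(10, 6)))
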