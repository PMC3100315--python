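import numpy as np
import pandas as pd
import pytest

from xsub import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with distinct, easily recognizable values."""
    data = pd.DataFrame(
        [[1.5, 2.25], [-0.5, 4.0], [3.0, 0.125]],
        index=["PDGFRA", "OLIG2", "CSPG4"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def make_matrix(values, genes=None, samples=None, **kwargs) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), **kwargs)
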