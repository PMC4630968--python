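import numpy as np
import pytest

import zifa


@pytest.fixture
def tiny_matrix():
    """3 cells x 2 genes with one exact zero."""
    return zifa.ExpressionMatrix(
        values=np.array([[1.5, 0.0], [2.25, 3.125], [0.5, 1.75]]),
        cell_ids=["c1", "c2", "c3"],
        gene_ids=["g1", "g2"],
    )


@pytest.fixture
def small_params():
    rng = np.random.default_rng(42)
    return zifa.ModelParams(
        A=rng.uniform(-0.5, 0.5, size=(3, 1)),
        mu=[3.0, 2.8, 2.5],
        sigma2=[0.3, 0.5, 0.4],
        lam=0.3,
    )


@pytest.fixture
def base_sim():
    """One draw of the standard simulation setting (N=150, D=50, K=10)."""
    return zifa.simulate_factor_data(seed=11)
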