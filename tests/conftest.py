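import numpy as np
import pytest

from fdmoments.panels import ExpressionPanel, ResidualPanel, residualize


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_panel(rng):
    """10 x 6 expression panel with groups (3, 3)."""
    values = np.exp(rng.normal(5.0, 1.0, size=(10, 6)))
    return ExpressionPanel(
        values=values,
        gene_ids=[f"g{i}" for i in range(10)],
        groups=[1, 1, 1, 2, 2, 2],
    )


@pytest.fixture
def gaussian_panel(rng):
    """50 x 10 log-scale panel of iid normals, groups (5, 5)."""
    return ExpressionPanel(
        values=rng.standard_normal((50, 10)),
        gene_ids=[f"g{i}" for i in range(50)],
        groups=[1] * 5 + [2] * 5,
        log_transformed=True,
    )


@pytest.fixture
def residual_rows():
    """Factory: ResidualPanel of iid-normal residualized rows."""

    def make(G, M, seed=0, groups=None):
        r = np.random.default_rng(seed)
        groups = groups or (M // 2, M - M // 2)
        panel = ExpressionPanel(
            values=r.standard_normal((G, M)),
            gene_ids=[f"g{i}" for i in range(G)],
            groups=[1] * groups[0] + [2] * groups[1],
            log_transformed=True,
        )
        return residualize(panel)

    return make
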