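import numpy as np
import pandas as pd
import pytest

from glycohub.io import ExpressionMatrix


def make_expression(
    values: np.ndarray,
    genes=None,
    cohort: str = "c1",
    region: str = "r1",
    n_case: int | None = None,
) -> ExpressionMatrix:
    """Small ExpressionMatrix with the first half of samples as cases."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes if genes is not None else [f"g{i}" for i in range(n_genes)]
    n_case = n_case if n_case is not None else n_samples // 2
    ids = [f"{cohort}_{region}_s{i}" for i in range(n_samples)]
    meta = pd.DataFrame(
        {
            "cohort": cohort,
            "region": region,
            "condition": ["case"] * n_case + ["control"] * (n_samples - n_case),
        },
        index=ids,
    )
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=ids), meta)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
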