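import numpy as np
import pandas as pd
import pytest

from coexsurv.io import ExpressionMatrix, SurvivalTable


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples with exact linear relations to SEEDX."""
    samples = tuple(f"S{i}" for i in range(1, 7))
    seed = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    return ExpressionMatrix(
        gene_ids=("SEEDX", "POS", "NEG", "NOISE"),
        sample_ids=samples,
        values=np.vstack([
            seed,
            2.0 * seed + 1.0,      # r = +1
            10.0 - seed,           # r = -1
            np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0]),
        ]),
    )


@pytest.fixture
def toy_survival() -> SurvivalTable:
    return SurvivalTable(pd.DataFrame({
        "sample": [f"S{i}" for i in range(1, 7)],
        "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
        "event": [1, 1, 0, 1, 0, 1],
    }))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
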