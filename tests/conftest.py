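import numpy as np
import pytest
from hypothesis import settings

from tissuescreen import ExpressionPanel

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_panel(rng):
    """10 genes x 5 tissues of positive random TPM."""
    values = rng.lognormal(0.5, 1.0, size=(10, 5))
    return ExpressionPanel(
        database_name="testdb",
        gene_ids=[f"G{i}" for i in range(10)],
        gene_symbols=[f"sym{i}" for i in range(10)],
        tissue_labels=[f"t{j}" for j in range(5)],
        values=values,
    )
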