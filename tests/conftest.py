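import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20110607)


@pytest.fixture
def small_matrix_tsv(tmp_path):
    """Well-formed 2-gene, n = 2 paired matrix file."""
    path = tmp_path / "matrix.tsv"
    path.write_text(
        "gene_id\tR_1\tR_2\tG_1\tG_2\n"
        "geneA\t10\t20\t30\t40\n"
        "geneB\t5\t0\t0\t5\n"
    )
    return path
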