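import numpy as np
import pytest

from mignet.expression import ExpressionMatrix


def make_matrix(values, experiments=None, gene_prefix="g", chip_prefix="c"):
    """ExpressionMatrix from a plain array, with optional experiment labels."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    gene_ids = [f"{gene_prefix}{i}" for i in range(n)]
    chip_ids = [f"{chip_prefix}{j}" for j in range(m)]
    if experiments is None:
        experiments = ["e0"] * m
    return ExpressionMatrix(
        gene_ids=gene_ids,
        chip_ids=chip_ids,
        experiment_of_chip=dict(zip(chip_ids, experiments)),
        values=values,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def random_matrix(rng):
    """12 genes x 40 chips of i.i.d. noise across two experiments."""
    values = rng.standard_normal((12, 40))
    return make_matrix(values, experiments=["eA"] * 25 + ["eB"] * 15)
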