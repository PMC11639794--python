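"""Shared fixtures: small matrices and the default seeded synthetic atlas."""

import numpy as np
import pandas as pd
import pytest

from tissueatlas import ExpressionMatrix, generate_atlas
from tissueatlas.simulate import DEFAULT_TISSUES

ATLAS_SEED = 42


@pytest.fixture(scope="session")
def atlas():
    """Default synthetic atlas (3000 genes x 11 tissues) with planted truth."""
    return generate_atlas(seed=ATLAS_SEED)


@pytest.fixture(scope="session")
def network_input(atlas):
    """Log2 expression of the planted module genes plus background genes."""
    matrix, truth = atlas
    module_genes = [g for genes in truth.module_map.values() for g in genes]
    background = [g for g in matrix.data.index if g.startswith("BG")][:400]
    ids = module_genes + background
    log_expr = pd.DataFrame(
        np.log2(matrix.subset(ids).values + 1.0),
        index=ids,
        columns=matrix.tissue_labels,
    )
    return log_expr, truth


@pytest.fixture
def small_matrix():
    """3 genes x 11 tissues with the default tissue panel."""
    data = pd.DataFrame(
        [
            np.linspace(1.0, 11.0, 11),
            np.full(11, 5.0),
            np.r_[np.zeros(10), 100.0],
        ],
        index=["g1", "g2", "g3"],
        columns=list(DEFAULT_TISSUES),
    )
    return ExpressionMatrix(data)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
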