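import numpy as np
import pandas as pd
import pytest

from statecrosstalk.io import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_matrix(values, genes=None, cells=None, layer="cpm", compartment=None, state=None):
    """Small ExpressionMatrix helper used across the suite."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    cells = cells or [f"c{j}" for j in range(n_cells)]
    meta = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    if compartment is not None:
        meta["compartment"] = compartment
    if state is not None:
        meta["state"] = state
    return ExpressionMatrix(values, np.array(genes, dtype=object),
                            np.array(cells, dtype=object), layer=layer, cell_meta=meta)


@pytest.fixture
def tiny_counts():
    return make_matrix([[5, 0], [15, 10], [30, 10]], layer="counts")
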