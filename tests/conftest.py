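import numpy as np
import pandas as pd
import pytest

from cardiomap.containers import GeneExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    """Random sparse-ish 30-gene x 40-cell count matrix over two replicates."""
    counts = rng.poisson(1.5, size=(30, 40))
    counts[rng.random(counts.shape) < 0.4] = 0
    gene_ids = [f"g{i:03d}" for i in range(30)]
    cell_ids = [f"c{i:03d}" for i in range(40)]
    meta = pd.DataFrame({"replicate": ["R1"] * 20 + ["R2"] * 20}, index=cell_ids)
    return GeneExpressionMatrix(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta
    )


def make_matrix(counts, replicates=None):
    counts = np.asarray(counts)
    ng, nc = counts.shape
    gene_ids = [f"g{i:03d}" for i in range(ng)]
    cell_ids = [f"c{i:03d}" for i in range(nc)]
    reps = list(replicates) if replicates is not None else ["R1"] * nc
    meta = pd.DataFrame({"replicate": reps}, index=cell_ids)
    return GeneExpressionMatrix(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta
    )
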