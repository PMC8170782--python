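import numpy as np
import pytest

from citegraph.io import ExpressionMatrix
from citegraph.model import ModelConfig, init_params


@pytest.fixture
def tiny_instance():
    """A fixed small model instance: G=6, N=3, M=2, d_r=2, d_c=2, seeded weights."""
    rng = np.random.default_rng(42)
    config = ModelConfig(
        n_genes=6, n_proteins=3, n_prior_features=2, hidden=(4, 3), d_r=2, d_c=2
    )
    params = init_params(config, rng)
    priors = np.abs(rng.normal(size=(2, 3, 3)))
    priors = (priors + priors.transpose(0, 2, 1)) / 2
    for m in priors:
        np.fill_diagonal(m, 0.0)
    x = rng.normal(size=(4, 6))
    return config, params, priors, x


def make_qc_fixture(n_mito_violators: int = 7, n_low_gene: int = 5, n_total: int = 100):
    """100-cell expression fixture with known, non-overlapping QC violators.

    Gene 0 is mitochondrial.  Normal cells express 300 ordinary genes;
    rule-1 violators sit exactly at a 20% mitochondrial fraction; rule-2
    violators express exactly 250 genes with no mitochondrial signal.
    """
    n_genes = 401  # MT-1 plus 400 ordinary genes
    n_normal = n_total - n_mito_violators - n_low_gene
    values = np.zeros((n_total, n_genes))
    for c in range(n_normal):
        values[c, 1:301] = 1.0  # 300 genes, mito fraction 0
    for c in range(n_normal, n_normal + n_mito_violators):
        values[c, 1:301] = 1.0
        values[c, 0] = 75.0  # 75 / 375 = exactly 0.20
    for c in range(n_normal + n_mito_violators, n_total):
        values[c, 1:251] = 1.0  # exactly 250 genes expressed
    gene_ids = ["MT-1"] + [f"g{i}" for i in range(n_genes - 1)]
    cell_ids = [f"c{i}" for i in range(n_total)]
    return ExpressionMatrix(values, gene_ids, cell_ids)


@pytest.fixture
def qc_fixture():
    return make_qc_fixture()
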