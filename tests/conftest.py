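"""Shared fixtures: small synthetic datasets generated once per session."""

import numpy as np
import pytest
import scipy.sparse as sp

from ifndirect import (CountMatrix, GeneratorConfig, RunConfig,
                       generate_datasets)

#: compact generator: every panel/program gene present, few filler genes,
#: enough cells per subset for clustering-free statistics
SMALL_KW = dict(n_cells_per_condition=600, n_genes=600, seed=11)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(**SMALL_KW)


@pytest.fixture(scope="session")
def small_datasets(small_config):
    return generate_datasets(small_config,
                             ["control", "dsDNA", "dsDNA_IFNARAb"])


@pytest.fixture()
def run_config() -> RunConfig:
    cfg = RunConfig()
    cfg.seed = 11
    cfg.simulate = GeneratorConfig(**SMALL_KW)
    return cfg


def dense_matrix(arr, genes=None, barcodes=None) -> CountMatrix:
    """Build a CountMatrix from a dense list/array with default names."""
    arr = np.asarray(arr)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    barcodes = barcodes or [f"C{i}" for i in range(arr.shape[1])]
    return CountMatrix(sp.csr_matrix(arr), genes, barcodes)

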