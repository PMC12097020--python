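import anndata as ad
import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from covpanel import PositivityMatrix, SimConfig


@pytest.fixture
def t6():
    """Six-cell toy positivity matrix with hand-countable unions.

    Positive sets: c1={a}, c2={b}, c3={c}, c4={a,b}, c5={}, c6={a,c}.
    """
    flags = pd.DataFrame(
        {
            "a": [1, 0, 0, 1, 0, 1],
            "b": [0, 1, 0, 1, 0, 0],
            "c": [0, 0, 1, 0, 0, 1],
        },
        index=[f"c{i}" for i in range(1, 7)],
    )
    return PositivityMatrix(flags=flags, rule={"modality": "toy"})


@pytest.fixture
def small_sim():
    """A small but fully featured cohort configuration."""
    return SimConfig(
        seed=11,
        n_patients=2,
        cells_per_patient=400,
        n_background_genes=3000,
        t_cell_count=100,
        n_timepoints=5,
    )


def adata_from_counts(counts, mito=None, barcodes=None, genes=None):
    """Assemble a minimal AnnData with the metadata QC expects."""
    counts = np.asarray(counts)
    n, g = counts.shape
    barcodes = barcodes or [f"cell{i}" for i in range(n)]
    genes = genes or [f"g{j}" for j in range(g)]
    obs = pd.DataFrame(
        {
            "mito_fraction": mito if mito is not None else np.zeros(n),
            "detected_genes": (counts > 0).sum(axis=1),
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int32)),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
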