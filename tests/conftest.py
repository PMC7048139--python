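import numpy as np
import pandas as pd
import pytest

import tcellex as tx

#: QC thresholds scaled to the synthetic panel (~570 genes, not a full
#: transcriptome): a healthy cell detects ~300-450 panel genes, a planted
#: low-quality cell ~100.
PANEL_MIN_GENES = 150


@pytest.fixture(scope="session")
def cell_spec():
    return tx.default_cell_spec()


@pytest.fixture(scope="session")
def tcell_dataset(cell_spec):
    """Default-condition single-cell dataset, 1000 cells, melanoma flavor."""
    return tx.make_tcell_dataset(cell_spec, 1000, seed=7)


@pytest.fixture(scope="session")
def bulk_cohort():
    """Default-condition bulk cohort with planted hazard and response effects."""
    return tx.make_bulk_cohort(tx.CohortSpec(seed=3))


def tiny_matrix(rows: dict, flavor: str = "log2_tpm10") -> tx.ExpressionMatrix:
    """Hand-built gene x cell matrix from {gene: [values]}."""
    df = pd.DataFrame(rows, dtype=float).T
    df.columns = [f"c{i}" for i in range(df.shape[1])]
    return tx.ExpressionMatrix(df, flavor)


@pytest.fixture
def make_tiny_matrix():
    return tiny_matrix
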