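import numpy as np
import pandas as pd
import pytest

from climenet.datatypes import (
    STATUS_OK,
    CtTable,
    ExpressionMatrix,
    gene_names,
    sample_meta,
)


def make_expression(values, stage="S1", batch="B1", scale="ratio", condition="control"):
    """ExpressionMatrix from a plain 2-D array with generated ids."""
    values = np.asarray(values, dtype=float)
    genes = gene_names(values.shape[0])
    cols = [f"S{i+1:03d}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=genes, columns=cols)
    return ExpressionMatrix(frame, sample_meta(cols, stage, batch, condition), scale)


def make_ct(values, status=None, stage="S1", batch="B1"):
    """CtTable from a plain 2-D array (status defaults to all-ok)."""
    values = np.asarray(values, dtype=float)
    genes = gene_names(values.shape[0])
    cols = [f"S{i+1:03d}" for i in range(values.shape[1])]
    vframe = pd.DataFrame(values, index=genes, columns=cols)
    if status is None:
        status = np.full(values.shape, STATUS_OK, dtype=object)
    sframe = pd.DataFrame(np.asarray(status, dtype=object), index=genes, columns=cols)
    return CtTable(vframe, sframe, sample_meta(cols, stage, batch))


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
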