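import numpy as np
import pandas as pd
import pytest

from evbal import QuantMatrix, SampleMetadata


def make_metadata(n_control: int, n_cancer: int, **overrides) -> SampleMetadata:
    """Minimal valid metadata: controls then cancer cases, constant covariates
    unless overridden with full-length lists."""
    n = n_control + n_cancer
    base = {
        "cancer_status": ["NO"] * n_control + ["YES"] * n_cancer,
        "gender": ["F"] * n,
        "smoking": ["non"] * n,
        "batch": [1] * n,
        "stage": ["no"] * n_control + ["NA"] * n_cancer,
        "vital_status": ["alive"] * n,
        "age_group": ["NA"] * n,
    }
    base.update(overrides)
    idx = [f"S{i+1}" for i in range(n)]
    return SampleMetadata(pd.DataFrame(base, index=idx))


def make_quant(values, sample_ids=None, protein_ids=None, gene_symbols=None) -> QuantMatrix:
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    sample_ids = sample_ids or [f"S{j+1}" for j in range(m)]
    protein_ids = protein_ids or [f"P{i+1}" for i in range(n)]
    gene_symbols = gene_symbols or [f"G{i+1}" for i in range(n)]
    return QuantMatrix(
        pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        pd.Series(gene_symbols, index=protein_ids),
    )


@pytest.fixture
def toy_quant():
    return make_quant([[2, 3], [4, 5], [6, 7]])
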