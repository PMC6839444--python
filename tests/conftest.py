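import numpy as np
import pandas as pd
import pytest

from mircohort.qpcr import CtMatrix, ExpressionMatrix, NormalizedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20190242)


@pytest.fixture
def small_ct_matrix(rng):
    """6 assays x 8 samples, complete, Ct around 25."""
    ct = 25.0 + rng.normal(0, 1.5, size=(6, 8))
    return CtMatrix(
        ct=pd.DataFrame(
            ct,
            index=[f"miR-{i:02d}" for i in range(6)],
            columns=[f"S{j}" for j in range(8)],
        )
    )


@pytest.fixture
def small_expression(rng):
    """10 assays x 12 samples of positive rq values."""
    rq = np.exp(rng.normal(0, 0.5, size=(10, 12)))
    return ExpressionMatrix(
        rq=pd.DataFrame(
            rq,
            index=[f"miR-{i:02d}" for i in range(10)],
            columns=[f"S{j}" for j in range(12)],
        ),
        reference_samples=[f"S{j}" for j in range(4)],
    )


def make_expression(values, assay_ids=None, sample_ids=None, reference=None):
    values = np.asarray(values, dtype=float)
    assay_ids = assay_ids or [f"a{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        rq=pd.DataFrame(values, index=assay_ids, columns=sample_ids),
        reference_samples=reference or [],
    )


def make_normalized(dct, sample_offsets=None):
    dct = pd.DataFrame(dct)
    if sample_offsets is None:
        sample_offsets = pd.Series(0.0, index=dct.columns)
    return NormalizedMatrix(dct=dct, sample_offsets=sample_offsets)
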