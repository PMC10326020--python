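import numpy as np
import pandas as pd
import pytest

from crosslasso.containers import OmicsMatrix, PairedInput


def make_matrix(values, analyte_ids=None, condition_ids=None, assay="other",
                gene_symbols=None, condition_groups=None):
    """Small OmicsMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    r, c = values.shape
    if analyte_ids is None:
        analyte_ids = [f"a{i}" for i in range(r)]
    if condition_ids is None:
        condition_ids = [f"c{j}" for j in range(c)]
    if gene_symbols is None:
        gene_symbols = [f"G_{a}" for a in analyte_ids]
    meta = pd.DataFrame(
        {"gene_symbol": gene_symbols, "assay": assay},
        index=pd.Index(analyte_ids, name="analyte_id"),
    )
    return OmicsMatrix(
        values=values,
        analyte_ids=list(analyte_ids),
        analyte_meta=meta,
        condition_ids=list(condition_ids),
        condition_groups=condition_groups or {},
    )


def make_pair(left_values, right_values, **kw):
    c = np.asarray(left_values).shape[1]
    cids = kw.pop("condition_ids", [f"c{j}" for j in range(c)])
    groups = kw.pop("condition_groups", {})
    left = make_matrix(left_values, analyte_ids=[f"y{i}" for i in range(len(left_values))],
                       condition_ids=cids, assay="rppa", condition_groups=groups)
    right = make_matrix(right_values, analyte_ids=[f"x{i}" for i in range(len(right_values))],
                        condition_ids=cids, assay="rnaseq", condition_groups=groups)
    return PairedInput(left=left, right=right)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
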