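import numpy as np
import pandas as pd
import pytest

from hemangiomics import ExpressionMatrix, SampleSheet


@pytest.fixture
def tiny_matrix():
    """3 features x 2 samples."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [2.0, 1.0, 3.0], "s2": [4.0, 3.0, 5.0]},
                     index=["g1", "g2", "g3"]))


@pytest.fixture
def two_group_matrix():
    """One feature, groups A=(1,2,3) and B=(4,5,6)."""
    cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
    m = ExpressionMatrix(pd.DataFrame([[1.0, 2, 3, 4, 5, 6]],
                                      index=["g1"], columns=cols))
    groups = {c: ("A" if c.startswith("a") else "B") for c in cols}
    return m, groups


def group_means(matrix, sheet: SampleSheet, group: str) -> pd.Series:
    cols = sheet.samples_in(group)
    return matrix.data[cols].mean(axis=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
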