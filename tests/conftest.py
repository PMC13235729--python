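import numpy as np
import pandas as pd
import pytest

from regtriplets.io import ExpressionCohort


@pytest.fixture
def tiny_cohort():
    """3 genes x 4 samples with one gene of each class."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [0.5, 1.5, 2.5, 3.5], [4.0, 3.0, 2.0, 1.0]],
        index=["lncA", "ssgB", "immC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    classes = pd.Series({"lncA": "lncRNA", "ssgB": "SSG", "immC": "immune"})
    return ExpressionCohort(values, classes)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
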