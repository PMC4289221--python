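import numpy as np
import pandas as pd
import pytest

from ersubgroups import ExpressionMatrix
from ersubgroups.simulate import PairedDesign


@pytest.fixture
def small_matrix():
    """3 features x 4 samples, plain values."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [5.0, 5.0, 5.0, 5.0],
         [2.0, 1.0, 4.0, 3.0]],
        index=["gA", "gB", "gC"], columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def paired_toy():
    """Three tumors with (pre, post) pairs (1.0, 1.2), (5.0, 5.1), (9.0, 9.3)
    on one feature, plus a perfectly invariant and a constant feature."""
    pre = [1.0, 5.0, 9.0]
    post = [1.2, 5.1, 9.3]
    data = pd.DataFrame(
        {
            "T1_pre": [pre[0], 1.0, 7.0], "T2_pre": [pre[1], 4.0, 7.0],
            "T3_pre": [pre[2], 8.0, 7.0],
            "T1_post": [post[0], 1.0, 7.0], "T2_post": [post[1], 4.0, 7.0],
            "T3_post": [post[2], 8.0, 7.0],
        },
        index=["g_shift", "g_invariant", "g_constant"],
    )
    design = PairedDesign(("T1", "T2", "T3"),
                          ("T1_pre", "T2_pre", "T3_pre"),
                          ("T1_post", "T2_post", "T3_post"))
    return ExpressionMatrix(data), design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
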