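import numpy as np
import pandas as pd
import pytest

from evpanel import AbundanceMatrix


@pytest.fixture
def tiny_matrix() -> AbundanceMatrix:
    """3 genes x 4 samples, zero-inflated, hand-checkable."""
    data = pd.DataFrame(
        {
            "case1": [10.0, 0.0, 5.0],
            "case2": [12.0, 3.0, 6.0],
            "ctrl1": [2.0, 0.0, 7.0],
            "ctrl2": [4.0, 1.0, 8.0],
        },
        index=pd.Index(["A", "B", "C"], name="gene"),
    )
    groups = {"case1": "case", "case2": "case", "ctrl1": "ctrl", "ctrl2": "ctrl"}
    return AbundanceMatrix(data, groups)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170908)
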