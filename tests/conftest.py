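import numpy as np
import pandas as pd
import pytest

from mitoscreen import ExpressionMatrix, GeneList, PositionFrequencyMatrix, RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def small_matrix():
    """4 genes x 4 samples, linear scale, 2 WT + 2 KO."""
    values = pd.DataFrame(
        {
            "WT_1": [2.0, 4.0, 1.0, 8.0],
            "WT_2": [2.0, 4.0, 3.0, 8.0],
            "KO_1": [1.0, 4.0, 2.0, 16.0],
            "KO_2": [3.0, 4.0, 2.0, 16.0],
        },
        index=["GA", "GB", "GC", "GD"],
    )
    groups = {"WT_1": "WT", "WT_2": "WT", "KO_1": "KO", "KO_2": "KO"}
    return ExpressionMatrix(values=values, sample_groups=groups, scale="linear")


@pytest.fixture
def mito_list():
    return GeneList(name="mito", members=frozenset({"GA", "GB"}))


@pytest.fixture
def sharp_pwm():
    """Near-deterministic 6-mer with consensus ACGTAC."""
    counts = np.ones((4, 6))
    for j, base in enumerate("ACGTAC"):
        counts["ACGT".index(base), j] = 97
    return PositionFrequencyMatrix(name="TFX/TEST.01", family="TFX", counts=counts)
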