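import numpy as np
import pandas as pd
import pytest

from diffrac import ElutionMatrix, align_pair


def make_matrix(rows: dict, condition: str = "control") -> ElutionMatrix:
    """Build a small ElutionMatrix from {protein: profile} dicts."""
    df = pd.DataFrame.from_dict(rows, orient="index", dtype=float)
    df.columns = [f"f{i}" for i in range(1, df.shape[1] + 1)]
    df.index.name = "id"
    return ElutionMatrix(df, condition_label=condition)


@pytest.fixture
def small_pair():
    """Three proteins over four fractions; only B changes on treatment."""
    control = make_matrix(
        {"A": [5, 3, 0, 0], "B": [0, 4, 4, 0], "C": [1, 1, 1, 1]}, "control"
    )
    treated = make_matrix(
        {"A": [5, 3, 0, 0], "B": [0, 0, 4, 4], "C": [1, 1, 1, 1]}, "treated"
    )
    return align_pair(control, treated)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
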