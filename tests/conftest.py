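import numpy as np
import pandas as pd
import pytest

from cooccurnet import OccurrenceMatrix


@pytest.fixture
def tiny_matrix():
    """3 sites x 3 species: A at {1,2}, B at {2,3}, C at {1,2,3}."""
    df = pd.DataFrame(
        {"A": [1, 1, 0], "B": [0, 1, 1], "C": [1, 1, 1]},
        index=["s1", "s2", "s3"],
    )
    return OccurrenceMatrix.from_dataframe(df)


@pytest.fixture
def random_matrix():
    """20 sites x 10 species random binary matrix (every species occurs)."""
    rng = np.random.default_rng(42)
    while True:
        arr = (rng.random((20, 10)) < 0.4).astype(int)
        if arr.sum(axis=0).min() >= 1 and arr.sum(axis=1).min() >= 1:
            break
    df = pd.DataFrame(
        arr,
        index=[f"site{i}" for i in range(20)],
        columns=[f"sp{j}" for j in range(10)],
    )
    return OccurrenceMatrix.from_dataframe(df)


def occurrence_csv(tmp_path, df, name="occ.csv"):
    path = tmp_path / name
    df.to_csv(path)
    return path
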