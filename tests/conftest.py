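import numpy as np
import pandas as pd
import pytest

from omicnet import FeatureMatrix


@pytest.fixture
def small_counts() -> FeatureMatrix:
    """3 genes x 4 samples, two per phenotype group."""
    values = pd.DataFrame(
        [[10, 20, 30, 40], [5, 0, 15, 20], [100, 200, 300, 400]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    phen = {"s1": "NP", "s2": "NP", "s3": "AI-P", "s4": "AI-P"}
    return FeatureMatrix(values, "gene", phen)


@pytest.fixture
def twelve_sample_phenotype() -> pd.Series:
    samples = [f"s{i}" for i in range(12)]
    return pd.Series(["NP"] * 6 + ["AI-P"] * 6, index=samples)


def make_matrix(values: np.ndarray, kind: str, n_ref: int, n_other: int,
                prefix: str = "f", reference: str = "NP") -> FeatureMatrix:
    """Wrap a raw array as a FeatureMatrix with an NP/AI-P split."""
    n_feat = values.shape[0]
    samples = [f"s{i}" for i in range(n_ref + n_other)]
    phen = pd.Series(["NP"] * n_ref + ["AI-P"] * n_other, index=samples)
    df = pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(n_feat)], columns=samples
    )
    return FeatureMatrix(df, kind, phen, reference)


@pytest.fixture
def matrix_factory():
    return make_matrix
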