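import numpy as np
import pandas as pd
import pytest

from mirshift.diffexpr import CountMatrix
from mirshift.seedscan import MatureMiRNA


@pytest.fixture
def let7():
    """let-7-like mature sequence; seed GAGGUAG, 8mer match CUACCUCA."""
    return MatureMiRNA("let-7f", "UGAGGUAGUAGAUUGUAUAGUU")


@pytest.fixture
def rng():
    return np.random.default_rng(20230109)


def make_matrix(values, n_sham=None, lengths=None, features=None):
    """CountMatrix helper: first half of the columns sham, rest TAC."""
    arr = np.asarray(values, dtype=float)
    n_samples = arr.shape[1]
    if n_sham is None:
        n_sham = n_samples // 2
    samples = [f"s{i}" for i in range(n_sham)] + [
        f"t{i}" for i in range(n_samples - n_sham)
    ]
    if features is None:
        features = [f"g{i}" for i in range(arr.shape[0])]
    groups = pd.Series(
        ["sham"] * n_sham + ["TAC"] * (n_samples - n_sham), index=samples
    )
    if lengths is not None:
        lengths = pd.Series(np.asarray(lengths, dtype=float), index=features)
    return CountMatrix(
        pd.DataFrame(arr, index=features, columns=samples), groups, lengths
    )


def random_rna(rng, length):
    return "".join(np.array(list("ACGU"))[rng.integers(0, 4, size=length)])
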