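import numpy as np
import pandas as pd
import pytest

from sigscreen import ExpressionDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(values, genes=None, samples=None, groups=None):
    values = np.asarray(values, dtype=float)
    n_g, n_s = values.shape
    genes = genes or [f"g{i + 1}" for i in range(n_g)]
    samples = samples or [f"s{j + 1}" for j in range(n_s)]
    if groups is None:
        half = n_s // 2
        groups = {s: ("vehicle" if j < half else "treated") for j, s in enumerate(samples)}
    return ExpressionDataset(pd.DataFrame(values, index=genes, columns=samples), groups)


@pytest.fixture
def tiny_dataset():
    return make_dataset([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])


@pytest.fixture
def random_dataset(rng):
    return make_dataset(rng.normal(size=(50, 6)))


def ks_oracle(tag_positions, n):
    """Brute-force tag-KS: scan every rank position with explicit counts.

    Kept independent of the package's vectorized implementation so the two
    can cross-check each other.
    """
    tags = set(tag_positions)
    t = len(tags)
    a_best = float("-inf")
    b_best = float("-inf")
    seen = 0
    for pos in range(1, n + 1):
        if pos in tags:
            seen += 1
            a_best = max(a_best, seen / t - pos / n)
            b_best = max(b_best, pos / n - (seen - 1) / t)
    return a_best if a_best > b_best else -b_best
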