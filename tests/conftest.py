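import numpy as np
import pytest

from sscclust import ExpressionMatrix, LabelVector, SyntheticSpec, generate
from sscclust.preprocess import filter_informative_genes, log2_transform


@pytest.fixture(scope="session")
def easy_data():
    """Default ('easy regime') synthetic dataset with ground truth."""
    return generate(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def easy_work(easy_data):
    """The easy dataset after log2 transform and informative-gene filter."""
    expr, _ = easy_data
    return filter_informative_genes(log2_transform(expr))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 cells with two zeros, on counts scale."""
    values = np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 4.0]])
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2"], "counts")


def random_partition(rng, n, max_clusters):
    """Uniform random label vector, at least one cell per used label."""
    k = rng.integers(1, max_clusters + 1)
    labels = rng.integers(0, k, size=n)
    return LabelVector(labels)
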