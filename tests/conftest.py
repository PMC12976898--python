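import numpy as np
import pandas as pd
import pytest

from genemorph.expression import ExpressionMatrix
from genemorph.network import CoexpressionNetwork
from genemorph.morphology import SlideBag


@pytest.fixture
def toy_expr():
    """3 genes x 2 samples TPM toy."""
    return ExpressionMatrix(["A", "B", "C"], ["s1", "s2"], [[1, 2], [0, 0], [5, 5]])


@pytest.fixture
def separable_agg():
    agg = {"a": 1.0, "b": 2.0, "c": 10.0, "d": 11.0}
    labels = {"a": 0, "b": 0, "c": 1, "d": 1}
    return agg, labels


@pytest.fixture
def small_network():
    rng = np.random.default_rng(7)
    G = 5
    A = np.abs(rng.standard_normal((G, G)))
    A = 0.5 * (A + A.T)
    np.fill_diagonal(A, 0.0)
    return CoexpressionNetwork.from_adjacency([f"g{i}" for i in range(G)], A)


def make_bags(n_slides=8, n_patches=4, dim=6, seed=0, signal=3.0):
    """Tiny linearly separable bags for bookkeeping-level training tests."""
    rng = np.random.default_rng(seed)
    bags = []
    for i in range(n_slides):
        y = i % 2
        base = rng.standard_normal((n_patches, dim))
        base[:, 0] += signal * y
        bags.append(SlideBag(f"slide{i}", base, y))
    return bags


@pytest.fixture
def tiny_bags():
    return make_bags()


@pytest.fixture
def tiny_labels_frame(tiny_bags):
    return pd.DataFrame(
        {
            "slide_id": [b.slide_id for b in tiny_bags],
            "label": [b.label for b in tiny_bags],
            "high_confidence": [True] * len(tiny_bags),
        }
    )
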