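import numpy as np
import pytest

from scgrn.data_io import ExpressionMatrix, GoldNetwork

# Published benchmark ranking of the nine classifiers on three single-cell
# datasets under four CV schemes (rank 1 = best AUC in that combination).
# Used as input data for the average-rank computation.
PUBLISHED_RANKS = {
    # (dataset, scheme): ranks in METHOD_ORDER
    ("Data1", "loocv"): [1, 2, 3, 7, 8, 9, 5, 4, 6],
    ("Data2", "loocv"): [4, 6, 3, 2, 8, 7, 1, 9, 5],
    ("Data3", "loocv"): [4, 5, 3, 1, 8, 6, 2, 9, 7],
    ("Data1", "3fold"): [2, 1, 3, 9, 8, 7, 6, 5, 4],
    ("Data2", "3fold"): [4, 5, 3, 6, 8, 7, 2, 9, 1],
    ("Data3", "3fold"): [6, 4, 5, 1, 7, 3, 2, 9, 8],
    ("Data1", "5fold"): [3, 2, 1, 7, 8, 9, 5, 6, 4],
    ("Data2", "5fold"): [5, 6, 3, 2, 8, 7, 1, 9, 4],
    ("Data3", "5fold"): [3, 6, 5, 1, 8, 4, 2, 9, 7],
    ("Data1", "10fold"): [2, 1, 3, 6, 9, 7, 8, 4, 5],
    ("Data2", "10fold"): [5, 6, 3, 4, 8, 7, 1, 9, 2],
    ("Data3", "10fold"): [3, 5, 4, 1, 8, 6, 2, 9, 7],
}
METHOD_ORDER = ["svm_poly", "svm_rbf", "svm_linear", "rf", "dt", "gbdt", "knn", "lr", "nb"]
PUBLISHED_AVG_RANK = {
    "svm_poly": 3.5,
    "svm_rbf": 4.1,
    "svm_linear": 3.25,
    "rf": 3.9,
    "dt": 8.0,
    "gbdt": 6.6,
    "knn": 3.1,
    "lr": 7.6,
    "nb": 5.0,
}


@pytest.fixture
def tiny_expr():
    """4 genes x 5 cells, including the worked universe {A, g1, g2, g3}."""
    values = np.array(
        [
            [1.0, 0.0, 2.0, 1.5, 0.5],
            [3.0, 1.0, 0.0, 2.0, 1.0],
            [0.5, 0.5, 0.5, 0.5, 0.5],
            [2.0, 4.0, 1.0, 0.0, 3.0],
        ]
    )
    return ExpressionMatrix(("A", "g1", "g2", "g3"), tuple(f"c{i}" for i in range(5)), values)


@pytest.fixture
def tiny_net():
    return GoldNetwork(
        frozenset({("A", "g1"), ("A", "g3")}), frozenset({"A", "g1", "g2", "g3"})
    )


@pytest.fixture(scope="session")
def separable_problem():
    """Two well-separated Gaussian clusters, 20 samples x 6 features."""
    rng = np.random.default_rng(0)
    pos = rng.normal(3.0, 0.3, size=(10, 6))
    neg = rng.normal(-3.0, 0.3, size=(10, 6))
    X = np.vstack([pos, neg])
    y = np.array([1] * 10 + [-1] * 10)
    return X, y
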