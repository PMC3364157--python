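import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist, squareform

from incaclust import DistanceMatrix


def euclidean_dm(points) -> DistanceMatrix:
    """Euclidean distance matrix of a point configuration (rows = units)."""
    return DistanceMatrix(squareform(pdist(np.asarray(points, dtype=float))))


def distances_to(point, points) -> np.ndarray:
    return cdist(np.asarray(point, float)[None, :], np.asarray(points, float))[0]


def brute_force_w(phi2, delta2) -> float:
    """Independent numeric minimization of the INCA objective.

    Parameterizes the affine constraint by k-1 free weights and minimizes
    L(alpha) = sum_i alpha_i phi2_i - sum_{i<j} alpha_i alpha_j Delta2_ij
    numerically; used as the oracle for the linear-system solution.
    """
    phi2 = np.asarray(phi2, float)
    delta2 = np.asarray(delta2, float)
    k = len(phi2)
    if k == 1:
        return float(phi2[0])

    def objective(beta):
        a = np.append(beta, 1.0 - beta.sum())
        return a @ phi2 - 0.5 * a @ delta2 @ a

    best = np.inf
    for start in (np.full(k - 1, 1.0 / k), np.zeros(k - 1), np.eye(k - 1)[0] if k > 1 else None):
        if start is None:
            continue
        res = minimize(objective, start, method="BFGS", options={"gtol": 1e-12})
        best = min(best, res.fun)
    return float(best)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def three_tight_clusters(rng):
    """30 points in 3 tight, far-separated planar clusters (labels 1..3)."""
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    pts = np.vstack([c + 0.05 * rng.standard_normal((10, 2)) for c in centers])
    labels = np.repeat([1, 2, 3], 10)
    return pts, labels
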