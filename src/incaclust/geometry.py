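"""Distance-based group statistics and the INCA statistic.

Given a distance ``delta`` between units and a partition into groups
``C_1 .. C_k``, this module computes

* the geometric variability of each group,
  ``V(C_j) = (1 / (2 n_j^2)) * sum_{l,m} delta^2(g_l, g_m)`` — a
  distance-based analog of the within-group variance;
* the squared between-group distance
  ``Delta2_ij = mean cross-group delta^2 - V(C_i) - V(C_j)``, which equals
  the squared distance between group centroids when ``delta`` is Euclidean;
* the proximity of a unit g0 to a group,
  ``phi2(g0, C_j) = mean_l delta^2(g0, g_l) - V(C_j)`` — the squared
  distance from g0 to the group's "center";
* the INCA statistic ``W(g0) = min_alpha L(g0)`` over affine weights
  (``sum alpha_i = 1``), with
  ``L = sum_i alpha_i phi2_i - sum_{i<j} alpha_i alpha_j Delta2_ij``.
  Geometrically W is the squared orthogonal height of g0 above the
  hyperplane spanned by the group centers, and the projections
  ``U_j = phi2_j - W`` measure the in-hyperplane squared distance toward
  each center; the unit is allocated to the group with smallest U.

The minimizer is the stationary point of the Lagrange system
``[Delta2 1; 1' 0] [alpha; lam] = [phi2; 1]``; on the affine constraint the
objective is convex whenever the distance is Euclidean-embeddable.  When the
group centers affinely span the whole embedding space (k >= p + 1) the
system is singular-or-degenerate and W collapses to 0 for every unit — the
known limitation of the method; such results carry ``degenerate=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix, as_distance_matrix

__all__ = [
    "Partition",
    "GroupGeometry",
    "IncaStatistic",
    "geometric_variability",
    "between_group_distance",
    "proximity",
    "inca_statistic",
    "allocate",
]

#: relative tolerance under which a small negative W is clamped to zero
W_CLAMP_RTOL = 1e-8


@dataclass
class Partition:
    """Cluster labels ``1..k`` for n units.

    Any positive integer labels are accepted and remapped (with a warning)
    to consecutive ``1..k`` in sorted order.
    """

    labels: np.ndarray
    unit_ids: list | None = None
    k: int = field(init=False)
    sizes: np.ndarray = field(init=False)

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 1:
            raise ValueError("labels must be a 1-d vector")
        if not np.issubdtype(lab.dtype, np.integer):
            as_int = lab.astype(int)
            if not np.array_equal(as_int, lab.astype(float)):
                raise ValueError("labels must be integers")
            lab = as_int
        if (lab < 1).any():
            raise ValueError("labels must be >= 1")
        uniq = np.unique(lab)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            warnings.warn(
                f"labels {list(uniq)} are not consecutive 1..k; remapping",
                stacklevel=2,
            )
            lab = np.searchsorted(uniq, lab) + 1
        self.labels = lab
        self.k = len(uniq)
        self.sizes = np.bincount(lab, minlength=self.k + 1)[1:]

    @property
    def n(self) -> int:
        return len(self.labels)

    def members(self, j: int) -> np.ndarray:
        """Indices of group j (1-based group numbering)."""
        return np.where(self.labels == j)[0]

    def indicator(self) -> np.ndarray:
        """n x k 0/1 membership matrix."""
        Z = np.zeros((self.n, self.k))
        Z[np.arange(self.n), self.labels - 1] = 1.0
        return Z


def as_partition(part, n: int | None = None) -> Partition:
    if not isinstance(part, Partition):
        part = Partition(np.asarray(part))
    if n is not None and part.n != n:
        raise ValueError(f"partition labels length {part.n} does not match {n} units")
    return part


@dataclass
class GroupGeometry:
    """Per-group geometric variabilities and between-group squared distances."""

    variabilities: np.ndarray  # k, squared-distance units
    delta2: np.ndarray  # k x k symmetric, zero diagonal
    sizes: np.ndarray | None = None

    @property
    def k(self) -> int:
        return len(self.variabilities)


@dataclass
class IncaStatistic:
    """INCA statistic of one unit: height W, affine weights, projections U."""

    W: float
    alpha: np.ndarray
    U: np.ndarray
    phi2: np.ndarray
    degenerate: bool = False

    @property
    def k(self) -> int:
        return len(self.U)


def _group_stats(D2: np.ndarray, part: Partition):
    """Mean within/cross sums of squared distances.

    Returns (M, C): M[g, j] = mean_{b in C_j} D2[g, b] over all units g,
    and C[i, j] = mean over ordered cross pairs of D2 between groups i, j.
    """
    Z = part.indicator()
    M = (D2 @ Z) / part.sizes
    C = (Z.T @ D2 @ Z) / np.outer(part.sizes, part.sizes)
    return M, C


def geometric_variability(d, part) -> np.ndarray:
    """Geometric variability of each group (squared-distance units).

    ``V(C_j) = (1 / (2 n_j^2)) sum_{l,m} delta^2``, the double sum running
    over all ordered member pairs; singletons have V = 0.
    """
    D = as_distance_matrix(d)
    part = as_partition(part, D.n)
    _, C = _group_stats(D.values**2, part)
    return np.diag(C) / 2.0


def between_group_distance(d, part) -> GroupGeometry:
    """Squared distances between every pair of groups.

    ``Delta2_ij = mean cross delta^2 - V_i - V_j``; symmetric with zero
    diagonal.  Small negative entries can arise for non-Euclidean distances
    and are kept with a warning.
    """
    D = as_distance_matrix(d)
    part = as_partition(part, D.n)
    _, C = _group_stats(D.values**2, part)
    V = np.diag(C) / 2.0
    delta2 = C - V[:, None] - V[None, :]
    np.fill_diagonal(delta2, 0.0)
    if delta2.min(initial=0.0) < -1e-9 * max(delta2.max(initial=1.0), 1.0):
        warnings.warn(
            "negative squared between-group distance: the distance is not "
            "Euclidean-embeddable",
            stacklevel=2,
        )
    return GroupGeometry(V, 0.5 * (delta2 + delta2.T), part.sizes.copy())


def proximity(d_to_units, part, variabilities=None, d=None) -> np.ndarray:
    """Proximity ``phi2(g0, C_j)`` of a unit to each group.

    Parameters
    ----------
    d_to_units : (n,) array
        Distances from g0 to the n reference units.
    part : Partition or labels
    variabilities : (k,) array, optional
        Per-group geometric variabilities; computed from ``d`` if omitted.
    d : distance matrix, required when ``variabilities`` is None.
    """
    d0 = np.asarray(d_to_units, dtype=float)
    part = as_partition(part)
    if d0.ndim != 1 or len(d0) != part.n:
        raise ValueError(
            f"d_to_units has length {d0.size}, expected {part.n}"
        )
    if (d0 < 0).any():
        raise ValueError("distances to units must be non-negative")
    if variabilities is None:
        if d is None:
            raise ValueError("provide variabilities or the reference distance matrix")
        variabilities = geometric_variability(d, part)
    V = np.asarray(variabilities, dtype=float)
    Z = part.indicator()
    return (d0**2) @ Z / part.sizes - V


def _solve_w_batch(phi2: np.ndarray, delta2: np.ndarray, phi_scale=None):
    """Vectorized INCA statistic for a batch of units.

    phi2: (B, k) proximities; delta2: (k, k).  Returns (W, alpha, degenerate)
    with W shape (B,) and alpha shape (B, k).  Uses one LU factorization of
    the bordered Lagrange system for all units; singular systems fall back to
    the pseudo-inverse and are flagged degenerate.
    """
    phi2 = np.atleast_2d(np.asarray(phi2, dtype=float))
    B, k = phi2.shape
    if delta2.shape != (k, k):
        raise ValueError(f"delta2 shape {delta2.shape} does not match k={k}")
    if k == 1:
        W = phi2[:, 0].copy()
        return W, np.ones((B, 1)), False

    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = delta2
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    rhs = np.concatenate([phi2.T, np.ones((1, B))], axis=0)
    degenerate = False
    try:
        sol = np.linalg.solve(A, rhs)
        if not np.isfinite(sol).all():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        degenerate = True
        sol = np.linalg.pinv(A, rcond=1e-12) @ rhs
    alpha = sol[:k].T  # (B, k)
    W = np.einsum("bk,bk->b", alpha, phi2) - 0.5 * np.einsum(
        "bi,ij,bj->b", alpha, delta2, alpha
    )
    scale = np.abs(phi2).max(axis=1) if phi_scale is None else phi_scale
    tiny = (W < 0) & (W > -W_CLAMP_RTOL * np.maximum(scale, 1e-300))
    W[tiny] = 0.0
    if degenerate:
        W[:] = np.clip(W, 0.0, None)
    return W, alpha, degenerate


def inca_statistic(phi2, geom) -> IncaStatistic:
    """INCA statistic W(g0), affine weights alpha and projections U.

    ``phi2`` is the proximity vector of g0 to the k groups and ``geom`` the
    :class:`GroupGeometry` of the reference partition (only ``delta2`` is
    used).  For k = 1 the objective collapses to ``W = phi2_1`` with
    ``U = (0,)``.
    """
    phi2 = np.asarray(phi2, dtype=float).ravel()
    delta2 = geom.delta2 if isinstance(geom, GroupGeometry) else np.asarray(geom, float)
    delta2 = np.atleast_2d(delta2)
    W, alpha, degenerate = _solve_w_batch(phi2[None, :], delta2)
    W = float(W[0])
    alpha = alpha[0]
    U = phi2 - W
    return IncaStatistic(W=W, alpha=alpha, U=U, phi2=phi2, degenerate=degenerate)


def allocate(stat) -> int:
    """Allocate a typical unit to the group with the smallest projection U.

    Returns the 1-based group index; ties break toward the smallest index.
    """
    U = stat.U if isinstance(stat, IncaStatistic) else np.asarray(stat, dtype=float)
    return int(np.argmin(U)) + 1


def w_statistics(d, part, d_new=None):
    """INCA statistic W for many units against one reference partition.

    When ``d_new`` is None, scores every reference unit with its own row of
    ``d`` (self-inclusion: a unit's zero self-distance enters its proximity
    to its own group).  Otherwise ``d_new`` is an (m, n) array of distances
    from m query units to the n reference units.

    Returns ``(W, U, geom, degenerate)`` with W shape (m,), U shape (m, k).
    """
    D = as_distance_matrix(d)
    part = as_partition(part, D.n)
    geom = between_group_distance(D, part)
    if d_new is None:
        rows = D.values
    else:
        rows = np.atleast_2d(np.asarray(d_new, dtype=float))
        if rows.shape[1] != D.n:
            raise ValueError(
                f"query distances have {rows.shape[1]} columns, expected {D.n}"
            )
    Z = part.indicator()
    phi2 = (rows**2) @ Z / part.sizes - geom.variabilities
    W, _, degenerate = _solve_w_batch(phi2, geom.delta2)
    U = phi2 - W[:, None]
    return W, U, geom, degenerate
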