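"""Clustering back-ends used to generate candidate partitions.

The INCA index evaluates partitions; it does not produce them.  Partitions
for k = 2..K come either from Partitioning Around Medoids (PAM, implemented
here as the classical BUILD + SWAP algorithm on a precomputed distance
matrix) or from agglomerative linkage trees cut at k (delegated to
``scipy.cluster.hierarchy``): average (UPGMA), single, complete, weighted
(WPGMA) and ward (Lance-Williams Ward recurrence applied to squared
distances).
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distances import as_distance_matrix

__all__ = ["CLUSTER_METHODS", "pam", "cut_tree_partitions", "partitions_for_ks"]

LINKAGE_METHODS = ("average", "single", "complete", "ward", "weighted")
CLUSTER_METHODS = ("pam",) + LINKAGE_METHODS


def pam(d, k: int, max_iter: int = 100) -> np.ndarray:
    """Partitioning Around Medoids on a precomputed distance matrix.

    BUILD seeds k medoids greedily; SWAP repeatedly applies the single best
    improving (medoid, non-medoid) exchange until none improves the total
    distance to nearest medoids.  Deterministic.  Returns labels 1..k.
    """
    D = as_distance_matrix(d).values
    n = D.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k={k} must be in [1, n-1] for n={n}")

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=0)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        # gain of adding candidate c: sum of reductions of nearest distances
        gain = np.clip(nearest[:, None] - D, 0.0, None).sum(axis=0)
        gain[medoids] = -np.inf
        c = int(np.argmax(gain))
        medoids.append(c)
        nearest = np.minimum(nearest, D[:, c])

    medoids = np.array(medoids)
    for _ in range(max_iter):
        Dm = D[:, medoids]  # n x k
        order = np.argsort(Dm, axis=1)
        d1 = Dm[np.arange(n), order[:, 0]]
        closest = order[:, 0]
        d2 = Dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)

        best_delta, best_swap = -1e-12, None
        for mi in range(k):
            # cost change, for every candidate h, of replacing medoid mi by h
            lose = closest == mi
            new_near = np.where(lose[:, None], np.minimum(d2[:, None], D), np.minimum(d1[:, None], D))
            delta = d1.sum() - new_near.sum(axis=0)  # positive = improvement
            delta[medoids] = -np.inf
            h = int(np.argmax(delta))
            if delta[h] > best_delta:
                best_delta, best_swap = delta[h], (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    labels = np.argmin(D[:, medoids], axis=1)
    # renumber groups 1..k in order of first appearance for stable output
    _, first = np.unique(labels, return_index=True)
    remap = {old: new + 1 for new, old in enumerate(labels[np.sort(first)])}
    return np.array([remap[v] for v in labels])


def cut_tree_partitions(d, ks, method: str) -> dict[int, np.ndarray]:
    """Cut one agglomerative tree at each k in ``ks``; labels 1..k."""
    if method not in LINKAGE_METHODS:
        raise ValueError(f"unknown linkage {method!r}; expected one of {LINKAGE_METHODS}")
    D = as_distance_matrix(d).values
    cond = squareform(D, checks=False)
    if method == "ward":
        Z = linkage(cond**2, method="ward")
    else:
        Z = linkage(cond, method=method)
    out = {}
    for k in ks:
        lab = fcluster(Z, t=k, criterion="maxclust")
        uniq = np.unique(lab)
        out[k] = np.searchsorted(uniq, lab) + 1
    return out


def partitions_for_ks(d, ks, method: str = "pam") -> dict[int, np.ndarray]:
    """Partitions (labels 1..k) for every k in ``ks`` by the named method."""
    if method == "pam":
        return {k: pam(d, k) for k in ks}
    return cut_tree_partitions(d, ks, method)
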