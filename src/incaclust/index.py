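"""The INCA index, the index curve over k, and the number-of-clusters rule.

For a partition ``C_1..C_k`` the INCA index is the mean, over clusters, of
the fraction of members that are *well classified*: fix a cluster ``C_j``,
compute every unit's INCA statistic ``W_{C_j}(g)`` with respect to the
remaining clusters, take the largest value attained by any unit outside
``C_j`` as the threshold, and count the members of ``C_j`` strictly above
it.  Members of a real cluster stand high above the hyperplane spanned by
the other clusters' centers, while outsiders lie near it, so a genuine
k-cluster structure drives the index toward 1; structureless data leave it
low and flat.

Scanning k = 2..K with a clustering back-end yields the INCA curve; the
number of clusters is read off at the k after which the index shows its
largest decrease (see :func:`estimate_k` for the exact rule), and a low flat
curve signals the absence of cluster structure.  Units that repeatedly land
in tiny clusters (size <= L) can be flagged as noise and the curve
recomputed without them, which can unmask a hidden structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from . import cluster as _cluster
from .distances import as_distance_matrix
from .geometry import Partition, as_partition, w_statistics

__all__ = [
    "IncaIndexResult",
    "IncaCurve",
    "inca_index",
    "inca_curve",
    "estimate_k",
    "IncaClusterNumber",
]


@dataclass
class IncaIndexResult:
    """Per-cluster well-classified counts and the total INCA index."""

    well_class: np.ndarray  # N_j per cluster
    sizes: np.ndarray  # n_j
    thresholds: np.ndarray  # max height of outsiders, per cluster
    total: float  # INCA_k in [0, 1]

    @property
    def k(self) -> int:
        return len(self.sizes)

    def __str__(self):
        lines = ["INCA index"]
        for j in range(self.k):
            lines.append(
                f"  cluster {j + 1}: {self.well_class[j]}/{self.sizes[j]} well classified"
            )
        lines.append(f"  total: {100 * self.total:.2f}% well classified")
        return "\n".join(lines)


def inca_index(d, part) -> IncaIndexResult:
    """INCA index of a fixed partition (k >= 2).

    For k = 2 the reduced reference consists of a single cluster, where the
    statistic degenerates to the proximity to that cluster.
    """
    D = as_distance_matrix(d)
    part = as_partition(part, D.n)
    if part.k < 2:
        raise ValueError("the INCA index needs a partition into at least 2 clusters")

    labels = part.labels
    well = np.zeros(part.k, dtype=int)
    thresholds = np.zeros(part.k)
    for j in range(1, part.k + 1):
        keep = labels != j
        ref_labels = labels[keep]
        uniq = np.unique(ref_labels)
        ref_part = Partition(np.searchsorted(uniq, ref_labels) + 1)
        # distances of every unit to the reference units only
        W, _, _, _ = w_statistics(
            D.values[np.ix_(keep, keep)], ref_part, d_new=D.values[:, keep]
        )
        thr = W[keep].max()
        thresholds[j - 1] = thr
        well[j - 1] = int((W[~keep] > thr).sum())
    total = float(np.mean(well / part.sizes))
    return IncaIndexResult(well, part.sizes.copy(), thresholds, total)


@dataclass
class IncaCurve:
    """INCA index per k, optionally with a noise-filtered second curve."""

    ks: np.ndarray
    index_all: np.ndarray
    method: str
    partitions: dict = field(default_factory=dict)
    noise_flags: np.ndarray | None = None  # per-unit booleans
    index_denoised: np.ndarray | None = None
    unit_ids: list | None = None

    @property
    def noise_units(self) -> list:
        if self.noise_flags is None:
            return []
        idx = np.where(self.noise_flags)[0]
        if self.unit_ids is not None:
            return [self.unit_ids[i] for i in idx]
        return list(idx + 1)


def _index_for_partitions(D, partitions: dict[int, np.ndarray]) -> np.ndarray:
    return np.array([inca_index(D, partitions[k]).total for k in sorted(partitions)])


def inca_curve(
    d,
    K: int,
    method: str = "pam",
    user_partitions=None,
    L: int | None = None,
    noise_units=None,
) -> IncaCurve:
    """INCA index for partitions with k = 2..K clusters.

    Parameters
    ----------
    d : distance matrix
    K : largest number of clusters considered (2 <= K < n).
    method : one of ``pam``, ``average``, ``single``, ``complete``, ``ward``,
        ``weighted``, or ``"partition"`` with ``user_partitions`` — an
        (n, n_partitions) array whose columns are label vectors.
    L : int, optional
        Noise rule: a unit that falls, in any of the k = 2..K partitions,
        into a cluster of size <= L is flagged as noise; the remaining units
        are re-clustered for each k and a second curve reported.
    noise_units : sequence, optional
        Explicit noise units (indices, or ids when the matrix carries ids);
        mutually exclusive with ``L``.
    """
    D = as_distance_matrix(d)
    n = D.n
    ids = D.unit_ids

    if method == "partition":
        if user_partitions is None:
            raise ValueError('method="partition" requires user_partitions')
        cols = np.atleast_2d(np.asarray(user_partitions))
        if cols.shape[0] != n:
            cols = cols.T
        if cols.shape[0] != n:
            raise ValueError(
                f"user partitions must cover all {n} units, got shape {cols.shape}"
            )
        partitions = {}
        for c in range(cols.shape[1]):
            p = as_partition(cols[:, c], n)
            partitions[p.k] = p.labels
        ks = np.array(sorted(partitions))
    else:
        if not 2 <= K < n:
            raise ValueError(f"K={K} must satisfy 2 <= K < n={n}")
        ks = np.arange(2, K + 1)
        partitions = _cluster.partitions_for_ks(D, ks, method)

    index_all = _index_for_partitions(D, partitions)
    curve = IncaCurve(ks, index_all, method, partitions, unit_ids=ids)

    flags = None
    if L is not None and noise_units is not None:
        raise ValueError("give either L or an explicit noise_units list, not both")
    if L is not None:
        if L >= n:
            raise ValueError(f"L={L} must be smaller than n={n}")
        flags = np.zeros(n, dtype=bool)
        for k, lab in partitions.items():
            sizes = np.bincount(lab)
            flags |= sizes[lab] <= L
    elif noise_units is not None:
        flags = np.zeros(n, dtype=bool)
        for u in noise_units:
            if ids is not None and str(u) in ids:
                flags[ids.index(str(u))] = True
            else:
                flags[int(u)] = True

    if flags is not None:
        curve.noise_flags = flags
        keep = ~flags
        if flags.any():
            D_keep = D.values[np.ix_(keep, keep)]
            if method == "partition":
                den_parts = {}
                for lab in partitions.values():
                    sub = lab[keep]
                    uniq = np.unique(sub)
                    if len(uniq) >= 2:
                        den_parts[len(uniq)] = np.searchsorted(uniq, sub) + 1
            else:
                usable = ks[ks < keep.sum()]
                den_parts = _cluster.partitions_for_ks(D_keep, usable, method)
            curve.index_denoised = _index_for_partitions(D_keep, den_parts)
        else:
            curve.index_denoised = index_all.copy()
    return curve


def estimate_k(curve, ks=None, structure_threshold: float = 0.2):
    """Number-of-clusters decision from an INCA curve.

    Returns the k *before* the largest decrease of the index, or ``None``
    when the whole curve stays below ``structure_threshold`` (no cluster
    structure).  Two kinds of k are eligible to precede the decisive drop:
    any k inside the initial non-increasing run of the curve (a structure
    already resolved at k = 2 collapsing as it is over-split), and any k
    where the index has just risen (a peak).  Drops from a falling value
    that follows a higher peak are over-partitioning artifacts and are
    ignored.  Ties break toward the smallest k.
    """
    if isinstance(curve, IncaCurve):
        values = np.asarray(curve.index_all, dtype=float)
        ks = np.asarray(curve.ks)
    else:
        values = np.asarray(curve, dtype=float)
        ks = np.arange(2, len(values) + 2) if ks is None else np.asarray(ks)
    if len(values) < 2:
        raise ValueError("need an index for at least two values of k")
    if values.max() < structure_threshold:
        return None

    drops = values[:-1] - values[1:]
    prefix_end = 0  # last index of the initial non-increasing run
    while prefix_end + 1 < len(values) and values[prefix_end + 1] <= values[prefix_end]:
        prefix_end += 1
    eligible = [
        i
        for i in range(len(drops))
        if drops[i] > 0 and (i < prefix_end or (i > 0 and values[i] >= values[i - 1]))
    ]
    if not eligible:
        # monotone or flat curve: largest raw drop, else largest value
        if (drops > 0).any():
            return int(ks[int(np.argmax(drops))])
        return int(ks[int(np.argmax(values))])
    best = max(eligible, key=lambda i: (drops[i], -i))
    return int(ks[best])


class IncaClusterNumber(BaseEstimator):
    """Estimate the number of clusters in a distance matrix via the INCA curve.

    Scans k = 2..k_max with a clustering back-end, computes the INCA index
    of each partition, applies the largest-decrease rule and (optionally)
    the noise-unit filter.

    Parameters
    ----------
    k_max : int, default 10
        Largest number of clusters scanned.
    method : str, default "pam"
        Clustering back-end (see :func:`inca_curve`).
    L : int, optional
        Noise-cluster size bound; units falling in clusters of size <= L in
        any scanned partition are flagged and a denoised curve is computed.
    structure_threshold : float, default 0.2
        Curves entirely below this level are read as "no cluster structure".

    Attributes
    ----------
    curve_ : IncaCurve
    n_clusters_ : int or None
        Estimated number of clusters; None when no structure is detected.
    has_structure_ : bool
    labels_ : ndarray
        Labels of the partition at ``n_clusters_`` (when structure found).
    noise_mask_ : ndarray of bool, only with the noise filter active.
    """

    def __init__(self, k_max=10, method="pam", L=None, structure_threshold=0.2):
        self.k_max = k_max
        self.method = method
        self.L = L
        self.structure_threshold = structure_threshold

    def fit(self, X, y=None):
        D = as_distance_matrix(X)
        self.curve_ = inca_curve(D, self.k_max, method=self.method, L=self.L)
        self.n_clusters_ = estimate_k(
            self.curve_, structure_threshold=self.structure_threshold
        )
        self.has_structure_ = self.n_clusters_ is not None
        if self.L is not None:
            self.noise_mask_ = self.curve_.noise_flags
        if self.has_structure_:
            self.labels_ = self.curve_.partitions[self.n_clusters_]
        return self

    def fit_predict(self, X, y=None):
        """Fit and return the labels of the chosen partition."""
        self.fit(X)
        if not self.has_structure_:
            return np.ones(as_distance_matrix(X).n, dtype=int)
        return self.labels_
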