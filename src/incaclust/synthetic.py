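"""Synthetic data generators: module-structured expression, time courses,
and exact geometric configurations.

Three generators give every statistic in the package a controlled input:

* :func:`simulate_modules` emulates module-structured expression data in the
  signed-network convention: each module has a latent standard-normal
  profile over samples (an eigengene) and member genes correlated with it
  by ``gene = r * profile + sqrt(1 - r^2) * noise`` with r drawn uniformly
  from a membership range; noise genes are pure standard normal.
* :func:`simulate_time_course` produces 6-timepoint profiles in 8 shape
  classes (constant, slowly increasing, late-increasing, two up-down
  shapes, down-up, cyclic, down-up-constant) with i.i.d. Gaussian noise
  around fixed numeric templates.
* :func:`simplex_fixture` builds clusters at the vertices of a simplex with
  a probe at a known orthogonal height h above the vertex hyperplane, so
  the INCA statistic has the exact analytic value ``W = h^2`` at zero
  spread.

All generators are deterministic under ``seed`` and echo their parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .distances import DistanceMatrix

__all__ = [
    "SimulatedExpression",
    "TimeCourseSet",
    "simulate_modules",
    "simulate_time_course",
    "time_course_templates",
    "simplex_fixture",
]


@dataclass
class SimulatedExpression:
    """Samples-by-genes expression table with per-gene module labels."""

    values: pd.DataFrame  # n_samples x n_genes
    labels: np.ndarray  # module id per gene, 0 = noise
    eigengenes: np.ndarray  # n_samples x n_modules latent profiles
    params: dict

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_distance(self, metric: str = "euclidean") -> DistanceMatrix:
        """Distance matrix between genes (units = genes)."""
        X = self.values.to_numpy().T
        return DistanceMatrix(
            squareform(pdist(X, metric=metric)), list(self.values.columns)
        )


def simulate_modules(
    n_samples: int = 100,
    module_sizes=(480, 360, 360),
    cor_lo: float = 0.5,
    cor_hi: float = 0.9,
    n_noise: int = 0,
    seed: int | None = None,
    *,
    n_genes: int | None = None,
    proportions=None,
) -> SimulatedExpression:
    """Simulate module-structured expression data.

    Either give explicit ``module_sizes`` (and ``n_noise``), or give
    ``n_genes`` with module ``proportions``; genes not covered by the
    proportions become noise genes (so ``n_genes=1200`` with proportions
    ``(0.3, 0.3, 0.3)`` yields three modules of 360 genes and 120 noise
    genes).  Member genes correlate with their module's latent profile with
    coefficients drawn uniformly from ``[cor_lo, cor_hi]``.
    """
    if not 0 < cor_lo <= cor_hi < 1:
        raise ValueError(
            f"need 0 < cor_lo <= cor_hi < 1, got ({cor_lo}, {cor_hi})"
        )
    if proportions is not None:
        if n_genes is None:
            raise ValueError("proportions require n_genes")
        module_sizes = [int(round(p * n_genes)) for p in proportions]
        n_noise = n_genes - sum(module_sizes)
        if n_noise < 0:
            raise ValueError("proportions sum to more than 1")
    module_sizes = [int(s) for s in module_sizes]
    if any(s < 1 for s in module_sizes):
        raise ValueError("every module needs at least one gene")

    rng = np.random.default_rng(seed)
    n_mod = len(module_sizes)
    if n_mod > n_samples:
        raise ValueError("need at least as many samples as modules")
    # distinct modules: latent profiles are mutually orthogonal (random
    # rotation frame), centered, and scaled to unit sample variance
    G = rng.standard_normal((n_samples, n_mod))
    Q, _ = np.linalg.qr(G - G.mean(axis=0))
    eigengenes = Q * np.sqrt(n_samples)

    cols, labels = [], []
    for m, size in enumerate(module_sizes, start=1):
        r = rng.uniform(cor_lo, cor_hi, size=size)
        noise = rng.standard_normal((n_samples, size))
        cols.append(eigengenes[:, m - 1 : m] * r + np.sqrt(1 - r**2) * noise)
        labels += [m] * size
    if n_noise:
        cols.append(rng.standard_normal((n_samples, n_noise)))
        labels += [0] * n_noise

    X = np.concatenate(cols, axis=1)
    genes = [f"Gene.{i + 1}" for i in range(X.shape[1])]
    samples = [f"Sample.{i + 1}" for i in range(n_samples)]
    params = dict(
        n_samples=n_samples,
        module_sizes=tuple(module_sizes),
        cor_lo=cor_lo,
        cor_hi=cor_hi,
        n_noise=n_noise,
        seed=seed,
    )
    return SimulatedExpression(
        pd.DataFrame(X, index=samples, columns=genes),
        np.array(labels),
        eigengenes,
        params,
    )


# Numeric templates realizing the 8 verbal profile shapes over 6 timepoints:
# G1 constant; G2 monotone increasing with a small first-to-last difference
# (deliberately close to G1); G3 constant over 1-3 then increasing; G4
# up-down peaking at 2; G5 up-down peaking at 5; G6 down-up dipping at 3;
# G7 cyclic (max at 2, min at 5); G8 down-up dipping at 2, constant at 3-6.
_TEMPLATES = np.array(
    [
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],  # G1
        [1.0, 1.1, 1.2, 1.3, 1.4, 1.5],  # G2
        [1.0, 1.0, 1.0, 2.0, 3.0, 4.0],  # G3
        [1.0, 3.0, 2.0, 1.5, 1.0, 0.5],  # G4
        [1.0, 1.5, 2.0, 2.5, 3.0, 1.0],  # G5
        [3.0, 2.0, 1.0, 1.5, 2.5, 3.0],  # G6
        [1.0, 3.0, 2.0, 1.0, 0.0, 1.0],  # G7
        [3.0, 1.0, 2.0, 2.0, 2.0, 2.0],  # G8
    ]
)


def time_course_templates() -> np.ndarray:
    """The 8 x 6 matrix of class-mean time-course templates."""
    return _TEMPLATES.copy()


@dataclass
class TimeCourseSet:
    """Genes-by-timepoints table with profile-class labels 1..8."""

    values: pd.DataFrame
    labels: np.ndarray
    noise_sd: float
    params: dict

    def gene_distance(self, metric: str = "sqrt_euclidean") -> DistanceMatrix:
        """Distance matrix between gene profiles.

        The default ``"sqrt_euclidean"`` is the square root of the Euclidean
        distance (the classical "snowflake" transform): it is Euclidean-
        embeddable only in high dimension, so the INCA statistic does not
        collapse to zero even with 7-8 reference clusters on 6 timepoints —
        with the plain Euclidean distance the cluster centers affinely span
        the whole 6-dimensional space and every height W is identically 0
        (the k >= p degeneracy).  Any scipy ``pdist`` metric name is also
        accepted.
        """
        X = self.values.to_numpy()
        if metric == "sqrt_euclidean":
            d = np.sqrt(squareform(pdist(X)))
        else:
            d = squareform(pdist(X, metric=metric))
        return DistanceMatrix(d, list(self.values.index))


def simulate_time_course(
    genes_per_group: int = 15, noise_sd: float = 0.15, seed: int | None = None
) -> TimeCourseSet:
    """Time-course profiles in 8 shape classes over 6 timepoints.

    Each gene is its class template plus i.i.d. Gaussian noise of standard
    deviation ``noise_sd``.  Defaults give a 120 x 6 table.
    """
    if genes_per_group < 1:
        raise ValueError("genes_per_group must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    X = np.repeat(_TEMPLATES, genes_per_group, axis=0)
    X = X + noise_sd * rng.standard_normal(X.shape)
    labels = np.repeat(np.arange(1, 9), genes_per_group)
    names = [f"G{g}.{i + 1}" for g in range(1, 9) for i in range(genes_per_group)]
    times = [f"T{t}" for t in range(1, 7)]
    return TimeCourseSet(
        pd.DataFrame(X, index=names, columns=times),
        labels,
        noise_sd,
        dict(genes_per_group=genes_per_group, noise_sd=noise_sd, seed=seed),
    )


def simplex_fixture(
    k: int,
    dim: int,
    spread: float = 0.0,
    probe_offset: float = 1.0,
    n_per_cluster: int = 1,
    seed: int | None = None,
):
    """Clusters at simplex vertices with a probe at known orthogonal height.

    Places k clusters of ``n_per_cluster`` points around the scaled
    standard-basis vertices ``2 e_1 .. 2 e_k`` in ``dim``-dimensional space
    (requires ``k <= dim + 1``) and a probe at orthogonal distance
    ``probe_offset`` above the centroid of the vertex hyperplane (which
    requires ``k <= dim`` unless the offset is 0).  At ``spread = 0`` the
    INCA statistic of the probe is exactly ``W = probe_offset**2``.

    Returns ``(DistanceMatrix, labels, probe_distances, analytic_W)``.
    """
    if k > dim + 1:
        raise ValueError(f"k={k} clusters need dim >= {k - 1}")
    vertices = 2.0 * np.eye(k, dim)
    centroid = vertices.mean(axis=0)
    if probe_offset != 0.0:
        span = (vertices - vertices[0])[1:]  # (k-1, dim)
        # unit normal to the vertex hyperplane
        _, s, Vt = np.linalg.svd(span) if len(span) else (None, np.zeros(0), np.eye(dim))
        rank = int((s > 1e-12).sum())
        if rank >= dim:
            raise ValueError(
                "vertex hyperplane fills the space; a nonzero orthogonal "
                "offset is impossible (use probe_offset=0)"
            )
        normal = Vt[rank] if len(span) else np.eye(dim)[0]
        probe = centroid + probe_offset * normal
    else:
        probe = centroid.copy()

    rng = np.random.default_rng(seed)
    points = np.repeat(vertices, n_per_cluster, axis=0)
    if spread > 0:
        points = points + spread * rng.standard_normal(points.shape)
    labels = np.repeat(np.arange(1, k + 1), n_per_cluster)
    D = DistanceMatrix(squareform(pdist(points)))
    d_probe = cdist(probe[None, :], points)[0]
    return D, labels, d_probe, float(probe_offset**2)
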