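"""Bootstrap typicality test: is a new unit typical of the clusters, or novel?

The null hypothesis is that the candidate unit g0 is a typical member of
the fixed partition ``C_1..C_k``.  Its INCA statistic ``W(g0)`` — the
squared height above the hyperplane through the cluster centers — is
compared against the bootstrap distribution of W over the reference units:
each repetition draws ``n_boot`` units with replacement from the pooled
clusters, computes their W values, and rejects when the empirical p-value
``p = #{W_b >= W(g0)} / n_boot`` falls below ``alpha``.  The procedure runs
``10 * P`` repetitions and reports the percentage that reject; a unit
rejected in at least half of them (configurable) is declared atypical —
member of an unknown group — otherwise it is allocated to the cluster with
the smallest projection ``U_j = phi2_j - W``.

Sampling distributions of W are hard to obtain analytically for arbitrary
(mixed-data) distances, which is why the null is bootstrapped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .distances import as_distance_matrix
from .geometry import allocate, as_partition, w_statistics

__all__ = ["TypicalityResult", "inca_test", "IncaTypicality"]


@dataclass
class TypicalityResult:
    """Outcome of the INCA typicality test for one candidate unit."""

    W0: float  # INCA statistic of the candidate
    U: np.ndarray  # projections toward each cluster
    pct_under_alpha: float  # % of repetitions rejecting H0 (0..100)
    alpha: float
    n_boot: int  # bootstrap sample size per repetition
    P: int  # repetition multiplier (10 * P repetitions)
    atypical: bool
    allocation: int | None  # 1-based cluster, None when atypical
    seed: int | None
    degenerate: bool = False

    def __str__(self):
        lines = [
            "INCA test",
            f"  INCA statistic value = {self.W0:.6g}",
            "  U projections values:",
        ]
        for j, u in enumerate(self.U, start=1):
            lines.append(f"    U{j} = {u:.6g}")
        n_rep = 10 * self.P
        n_sig = round(self.pct_under_alpha / 100 * n_rep)
        lines.append(f"  significative tests for alpha={self.alpha:g}: {n_sig}")
        lines.append(f"  percentage under alpha: {self.pct_under_alpha:g}")
        if self.atypical:
            lines.append("  verdict: atypical (new group)")
        else:
            lines.append(f"  verdict: typical, allocated to cluster {self.allocation}")
        return "\n".join(lines)


def _bootstrap_pct(w_ref, W0, n_boot, P, alpha, seed, p_correction):
    """Percentage of 10P bootstrap repetitions whose empirical p < alpha."""
    n = len(w_ref)
    n_rep = 10 * P
    rejections = 0
    for r in range(n_rep):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=0 if seed is None else seed, spawn_key=(r,))
        )
        idx = rng.integers(0, n, size=n_boot)
        count = int((w_ref[idx] >= W0).sum())
        if p_correction:
            p = (1 + count) / (n_boot + 1)
        else:
            p = count / n_boot
        rejections += p < alpha
    return 100.0 * rejections / n_rep


def inca_test(
    d,
    part,
    d_test,
    n_boot: int = 1000,
    alpha: float = 0.05,
    P: int = 1,
    seed: int | None = None,
    reject_fraction: float = 0.5,
    p_correction: bool = False,
) -> TypicalityResult:
    """INCA typicality test of one candidate unit.

    Parameters
    ----------
    d : (n, n) distance matrix between the reference units.
    part : labels 1..k of the reference partition.
    d_test : (n,) distances from the candidate g0 to every reference unit.
    n_boot : bootstrap sample size per repetition (the test's ``np``).
    alpha : per-repetition significance level.
    P : the bootstrap is repeated ``10 * P`` times.
    seed : governs all resampling; repetition r uses an independent
        substream spawned from (seed, r).
    reject_fraction : overall verdict is "atypical" when at least this
        fraction of repetitions rejects.
    p_correction : use the (1 + count) / (n_boot + 1) p-value estimator
        instead of the plain proportion.

    Notes
    -----
    Reference units are scored with their own distance rows as given
    (self-inclusion, no leave-one-out), and every unit — including any
    duplicate of g0 present in the reference set — can be resampled.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha={alpha} must be in (0, 1)")
    if n_boot < 1 or P < 1:
        raise ValueError("n_boot and P must be >= 1")
    D = as_distance_matrix(d)
    part = as_partition(part, D.n)
    d_test = np.asarray(d_test, dtype=float).ravel()
    if len(d_test) != D.n:
        raise ValueError(f"d_test has length {len(d_test)}, expected {D.n}")

    w_ref, _, _, _ = w_statistics(D, part)
    W_arr, U_arr, _, degenerate = w_statistics(D, part, d_new=d_test[None, :])
    W0 = float(W_arr[0])
    U = U_arr[0]

    pct = _bootstrap_pct(w_ref, W0, n_boot, P, alpha, seed, p_correction)
    atypical = pct >= 100.0 * reject_fraction
    return TypicalityResult(
        W0=W0,
        U=U,
        pct_under_alpha=pct,
        alpha=alpha,
        n_boot=n_boot,
        P=P,
        atypical=atypical,
        allocation=None if atypical else allocate(U),
        seed=seed,
        degenerate=degenerate,
    )


class IncaTypicality(BaseEstimator):
    """Typicality classifier over a fixed reference partition.

    ``fit`` takes the reference distance matrix (metric="precomputed") or a
    raw feature table together with cluster labels; ``predict`` scores new
    units by their distances to the reference units, returning the allocated
    1-based cluster label or ``-1`` for atypical units (members of an
    unknown group) — in the spirit of novelty-detecting classifiers.

    Parameters
    ----------
    n_boot : int, default 1000
        Bootstrap sample size per repetition.
    alpha : float, default 0.05
        Per-repetition significance level.
    P : int, default 1
        The bootstrap is repeated ``10 * P`` times.
    reject_fraction : float, default 0.5
        Fraction of rejecting repetitions needed for an "atypical" verdict.
    metric : str, default "precomputed"
        "precomputed" expects square distances in ``fit`` and query-by-
        reference distances in ``predict``; any scipy ``pdist`` metric name
        (e.g. "euclidean", "cityblock") computes them from feature rows.
    p_correction : bool, default False
        Use the (1 + count) / (n_boot + 1) p-value estimator.
    random_state : int, optional
        Seed for all bootstrap resampling.

    Attributes
    ----------
    w_insample_ : ndarray
        INCA statistic of every reference unit (the bootstrap pool).
    partition_, n_features_in_, classes_
    """

    def __init__(
        self,
        n_boot=1000,
        alpha=0.05,
        P=1,
        reject_fraction=0.5,
        metric="precomputed",
        p_correction=False,
        random_state=None,
    ):
        self.n_boot = n_boot
        self.alpha = alpha
        self.P = P
        self.reject_fraction = reject_fraction
        self.metric = metric
        self.p_correction = p_correction
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float) if not hasattr(X, "values") else X
        if self.metric == "precomputed":
            self.D_ = as_distance_matrix(X)
        else:
            from scipy.spatial.distance import pdist, squareform

            self.X_fit_ = np.asarray(X, dtype=float)
            self.D_ = as_distance_matrix(
                squareform(pdist(self.X_fit_, metric=self.metric))
            )
        self.partition_ = as_partition(y, self.D_.n)
        self.w_insample_, _, self.geometry_, _ = w_statistics(self.D_, self.partition_)
        self.classes_ = np.arange(1, self.partition_.k + 1)
        return self

    def _query_rows(self, X):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.metric == "precomputed":
            return X
        from scipy.spatial.distance import cdist

        return cdist(X, self.X_fit_, metric=self.metric)

    def test(self, x) -> TypicalityResult:
        """Full typicality test of a single candidate unit."""
        row = self._query_rows(x)[0]
        return inca_test(
            self.D_,
            self.partition_,
            row,
            n_boot=self.n_boot,
            alpha=self.alpha,
            P=self.P,
            seed=self.random_state,
            reject_fraction=self.reject_fraction,
            p_correction=self.p_correction,
        )

    def score_samples(self, X):
        """INCA statistic W of each query unit (larger = farther from the
        cluster-center hyperplane)."""
        rows = self._query_rows(X)
        W, _, _, _ = w_statistics(self.D_, self.partition_, d_new=rows)
        return W

    def predict(self, X):
        """Allocated cluster label per query unit; -1 marks atypical units."""
        rows = self._query_rows(X)
        out = np.empty(rows.shape[0], dtype=int)
        for i, row in enumerate(rows):
            res = inca_test(
                self.D_,
                self.partition_,
                row,
                n_boot=self.n_boot,
                alpha=self.alpha,
                P=self.P,
                seed=self.random_state,
                reject_fraction=self.reject_fraction,
                p_correction=self.p_correction,
            )
            out[i] = -1 if res.atypical else res.allocation
        return out
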