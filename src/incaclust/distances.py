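"""Distance matrices for mixed, frequency and continuous data.

All constructors return a :class:`DistanceMatrix` — a validated symmetric
matrix of dissimilarities ``delta(g, g')`` with zero diagonal — the substrate
of every INCA statistic.  Units are always rows of the input table.

Four distances are provided:

* :func:`bhattacharyya_distance` for rows of frequencies (compositional
  profiles), the arc-cosine of the Bhattacharyya coefficient;
* :func:`gower_distance` for mixed continuous/binary/qualitative variables,
  with Gower's weighted treatment of missing values and the Euclidean-
  embeddable transform ``d = sqrt(2 (1 - s))``;
* :func:`mahalanobis_pairwise`, the Mahalanobis distance between every pair
  of rows using the pooled covariance (pseudo-inverted when singular);
* :func:`correlation_distance` between unit profiles.

Any other precomputed distance matrix can be wrapped in
:class:`DistanceMatrix` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DistanceMatrix",
    "MixedDataTable",
    "FrequencyTable",
    "bhattacharyya_distance",
    "gower_distance",
    "mahalanobis_pairwise",
    "correlation_distance",
]

SYMMETRY_TOL = 1e-8

VAR_KINDS = ("continuous", "binary", "qualitative")


def _as_2d(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-d table, got shape {arr.shape}")
    return arr


@dataclass
class DistanceMatrix:
    """A symmetric n x n matrix of dissimilarities with zero diagonal."""

    values: np.ndarray
    unit_ids: Sequence[str] | None = None

    def __post_init__(self):
        v = _as_2d(self.values)
        n, m = v.shape
        if n != m:
            raise ValueError(f"distance matrix must be square, got {n}x{m}")
        if np.isnan(v).any():
            i, j = np.argwhere(np.isnan(v))[0]
            raise ValueError(f"distance matrix contains NaN at cell ({i + 1}, {j + 1})")
        asym = np.abs(v - v.T).max(initial=0.0)
        if asym > SYMMETRY_TOL:
            raise ValueError(f"distance matrix not symmetric (max asymmetry {asym:.3g})")
        v = 0.5 * (v + v.T)
        if (v < 0).any():
            raise ValueError("distance matrix has negative entries")
        np.fill_diagonal(v, 0.0)
        self.values = v
        if self.unit_ids is not None:
            ids = [str(u) for u in self.unit_ids]
            if len(ids) != n:
                raise ValueError(f"{len(ids)} unit ids for {n} units")
            self.unit_ids = ids

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self):
        return self.values.shape

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)

    def to_frame(self) -> pd.DataFrame:
        ids = self.unit_ids or [f"U{i + 1}" for i in range(self.n)]
        return pd.DataFrame(self.values, index=ids, columns=ids)


def as_distance_matrix(d) -> DistanceMatrix:
    """Coerce an array / DataFrame / DistanceMatrix into a DistanceMatrix."""
    if isinstance(d, DistanceMatrix):
        return d
    if isinstance(d, pd.DataFrame):
        return DistanceMatrix(d.to_numpy(dtype=float), list(d.index))
    return DistanceMatrix(np.asarray(d, dtype=float))


# ---------------------------------------------------------------------------
# frequency profiles


@dataclass
class FrequencyTable:
    """n units described by rows of non-negative frequencies summing to 1."""

    values: np.ndarray
    unit_ids: Sequence[str] | None = None

    def __post_init__(self):
        v = _as_2d(self.values)
        neg = np.argwhere(v < 0)
        if neg.size:
            raise ValueError(f"negative frequency in row {neg[0, 0] + 1}")
        sums = v.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-8)[0]
        if bad.size:
            raise ValueError(
                f"row {bad[0] + 1} sums to {sums[bad[0]]:.10g}, expected 1"
            )
        self.values = v


def bhattacharyya_distance(freqs) -> DistanceMatrix:
    """Bhattacharyya distance between frequency profiles.

    ``d(i, j) = arccos sum_l sqrt(p_il * p_jl)``, in ``[0, pi/2]``: 0 for
    identical profiles, pi/2 for profiles with disjoint support.
    """
    ids = None
    if isinstance(freqs, pd.DataFrame):
        ids = list(freqs.index)
        freqs = freqs.to_numpy(dtype=float)
    if not isinstance(freqs, FrequencyTable):
        freqs = FrequencyTable(freqs, ids)
    root = np.sqrt(freqs.values)
    coef = np.clip(root @ root.T, 0.0, 1.0)
    d = np.arccos(coef)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, freqs.unit_ids)


# ---------------------------------------------------------------------------
# mixed variables (Gower)

_MISSING_STRINGS = {"", "na", "nan", "NA", "NaN", "<NA>"}


def _missing_mask(col: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(col), dtype=bool)
    for i, v in enumerate(col):
        if v is None:
            mask[i] = True
        elif isinstance(v, float) and np.isnan(v):
            mask[i] = True
        elif isinstance(v, str) and v.strip() in _MISSING_STRINGS:
            mask[i] = True
        elif v is pd.NA:
            mask[i] = True
    return mask


@dataclass
class MixedDataTable:
    """Units-by-variables table with per-column kind declarations.

    Columns are ``continuous`` (compared via range-scaled absolute
    difference), ``binary`` (1 = presence; absence-absence pairs carry no
    information and are dropped from Gower's coefficient) or ``qualitative``
    (state match / mismatch).  Missing entries are allowed anywhere and are
    excluded pair-by-pair (Gower's weighted similarity).
    """

    values: np.ndarray  # object array, n x m
    var_kinds: Sequence[str]
    unit_ids: Sequence[str] | None = None
    var_names: Sequence[str] | None = None
    ranges: np.ndarray = field(init=False)
    missing_mask: np.ndarray = field(init=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, var_kinds) -> "MixedDataTable":
        if isinstance(var_kinds, dict):
            var_kinds = [var_kinds[c] for c in df.columns]
        return cls(
            df.to_numpy(dtype=object),
            list(var_kinds),
            unit_ids=list(df.index),
            var_names=list(df.columns),
        )

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=object)
        if vals.ndim != 2:
            raise ValueError("expected a 2-d table")
        n, m = vals.shape
        kinds = list(self.var_kinds)
        if len(kinds) != m:
            raise ValueError(f"{len(kinds)} variable kinds for {m} columns")
        for k in kinds:
            if k not in VAR_KINDS:
                raise ValueError(f"unknown variable kind {k!r}; expected one of {VAR_KINDS}")
        miss = np.column_stack([_missing_mask(vals[:, l]) for l in range(m)])
        ranges = np.zeros(m)
        for l, kind in enumerate(kinds):
            obs = vals[~miss[:, l], l]
            if kind == "continuous":
                x = obs.astype(float)
                ranges[l] = float(x.max() - x.min()) if x.size else 0.0
            elif kind == "binary":
                x = obs.astype(float)
                if not np.isin(x, (0.0, 1.0)).all():
                    name = self.var_names[l] if self.var_names else f"column {l + 1}"
                    raise ValueError(f"binary variable {name} has values outside {{0, 1}}")
        self.values = vals
        self.var_kinds = kinds
        self.missing_mask = miss
        self.ranges = ranges

    @property
    def counts(self):
        """(m1, m2, m3): number of continuous, binary, qualitative columns."""
        k = list(self.var_kinds)
        return (k.count("continuous"), k.count("binary"), k.count("qualitative"))


def gower_distance(data, var_kinds=None) -> DistanceMatrix:
    """Gower distance for mixed variables, ``d_ij = sqrt(2 (1 - s_ij))``.

    The similarity ``s_ij`` averages, over the variables comparable for the
    pair, range-scaled agreement for continuous variables, presence matches
    for binary variables (absence-absence pairs are excluded from both
    numerator and denominator) and state matches for qualitative variables.
    Terms involving a missing value in either unit are dropped together with
    their denominator contribution.

    Parameters
    ----------
    data : MixedDataTable or DataFrame/array
        When not already a MixedDataTable, ``var_kinds`` must give the
        per-column kinds.
    """
    if not isinstance(data, MixedDataTable):
        if var_kinds is None:
            raise ValueError("var_kinds required when data is not a MixedDataTable")
        if isinstance(data, pd.DataFrame):
            data = MixedDataTable.from_frame(data, var_kinds)
        else:
            data = MixedDataTable(np.asarray(data, dtype=object), var_kinds)

    n, m = data.values.shape
    present = ~data.missing_mask
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for l, kind in enumerate(data.var_kinds):
        p = present[:, l]
        both = np.outer(p, p)
        col = data.values[:, l]
        if kind == "continuous":
            x = np.where(p, col, 0).astype(float)
            if data.ranges[l] > 0:
                sim = 1.0 - np.abs(x[:, None] - x[None, :]) / data.ranges[l]
            else:
                # constant variable: identical observed values, similarity 1
                sim = np.ones((n, n))
            num += np.where(both, sim, 0.0)
            den += both
        elif kind == "binary":
            x = np.where(p, col, 0).astype(float)
            pres = x == 1.0
            pp = both & np.outer(pres, pres)
            aa = both & np.outer(~pres, ~pres)
            num += pp
            den += both & ~aa
        else:  # qualitative
            eq = col[:, None] == col[None, :]
            num += both & eq
            den += both

    # a unit is always fully similar to itself, even when every variable is
    # missing or an absence-absence match
    off = ~np.eye(n, dtype=bool)
    if (den[off] == 0).any():
        i, j = np.argwhere((den == 0) & off)[0]
        raise ValueError(
            f"units {i + 1} and {j + 1} share no comparable variable"
        )
    s = np.divide(num, den, out=np.ones((n, n)), where=den > 0)
    if s.min() < -1e-9 or s.max() > 1 + 1e-9:
        raise AssertionError("Gower similarity outside [0, 1]")
    d = np.sqrt(np.clip(2.0 * (1.0 - s), 0.0, None))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, data.unit_ids)


# ---------------------------------------------------------------------------
# continuous tables

#: relative eigenvalue cutoff for pseudo-inverting a singular covariance
PINV_RCOND = 1e-10


def mahalanobis_pairwise(data) -> DistanceMatrix:
    """Mahalanobis distance between every pair of rows.

    Uses the covariance of the full table; a singular covariance is handled
    by its Moore-Penrose pseudo-inverse, which projects out redundant
    directions (duplicated columns, collinear variables).
    """
    ids = list(data.index) if isinstance(data, pd.DataFrame) else None
    X = _as_2d(np.asarray(data, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least two units")
    S = np.cov(X, rowvar=False)
    S = np.atleast_2d(S)
    if not np.any(np.diag(S) > 0):
        raise ValueError("table has zero variance in every column")
    VI = np.linalg.pinv(S, rcond=PINV_RCOND, hermitian=True)
    diff = X[:, None, :] - X[None, :, :]
    d2 = np.einsum("ijk,kl,ijl->ij", diff, VI, diff)
    d = np.sqrt(np.clip(d2, 0.0, None))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids)


def correlation_distance(data, transform: str = "sqrt") -> DistanceMatrix:
    """Correlation distance between unit profiles.

    ``transform="sqrt"`` (default) gives ``d = sqrt(2 (1 - r))``, which is
    Euclidean-embeddable and keeps the INCA statistic non-negative;
    ``transform="linear"`` gives the plain ``d = 1 - r``.
    """
    ids = list(data.index) if isinstance(data, pd.DataFrame) else None
    X = _as_2d(np.asarray(data, dtype=float))
    sd = X.std(axis=1)
    flat = np.where(sd == 0)[0]
    if flat.size:
        unit = ids[flat[0]] if ids else f"unit {flat[0] + 1}"
        raise ValueError(f"constant profile for {unit}: correlation undefined")
    r = np.clip(np.corrcoef(X), -1.0, 1.0)
    if transform == "sqrt":
        d = np.sqrt(np.clip(2.0 * (1.0 - r), 0.0, None))
    elif transform == "linear":
        d = 1.0 - r
    else:
        raise ValueError(f"unknown transform {transform!r}; use 'sqrt' or 'linear'")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(0.5 * (d + d.T), ids)
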