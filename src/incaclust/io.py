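"""Readers and writers for distance matrices, partitions and mixed tables.

Conventions: CSV (default) or TSV by file extension; a header row and a
unit-id first column everywhere; missing entries as empty fields or "NA";
partition labels are positive integers (non-consecutive labels are remapped
to 1..k with a warning); distance matrices must be square with matching
row/column ids and are symmetrized when the asymmetry is below 1e-8.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .distances import SYMMETRY_TOL, DistanceMatrix, MixedDataTable, VAR_KINDS
from .geometry import Partition

__all__ = [
    "read_distance_matrix",
    "write_distance_matrix",
    "read_partition",
    "write_partition",
    "read_partition_matrix",
    "read_mixed_table",
    "read_test_distances",
    "write_json",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a square delimited distance matrix with id row and column."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: distance matrix must be square, got {df.shape[0]}x{df.shape[1]}"
        )
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise ValueError(f"{path}: row ids do not match column ids")
    v = df.to_numpy(dtype=float)
    nan = np.argwhere(np.isnan(v))
    if nan.size:
        i, j = nan[0]
        raise ValueError(
            f"{path}: missing value at cell ({df.index[i]}, {df.columns[j]})"
        )
    asym = np.abs(v - v.T).max(initial=0.0)
    if asym > SYMMETRY_TOL:
        raise ValueError(f"{path}: matrix asymmetric (max asymmetry {asym:.3g})")
    if asym > 0:
        warnings.warn(f"{path}: symmetrizing (max asymmetry {asym:.3g})", stacklevel=2)
    return DistanceMatrix(0.5 * (v + v.T), list(df.index.astype(str)))


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path, sep=_sep(path), index_label="id")


def read_partition(path, unit_ids=None) -> Partition:
    """Read a two-column (unit id, integer label >= 1) partition file.

    When ``unit_ids`` is given the rows are aligned to that order.
    """
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (unit id, label)")
    ids = df.iloc[:, 0].astype(str)
    labels = df.iloc[:, 1]
    if unit_ids is not None:
        order = pd.Series(np.arange(len(ids)), index=ids)
        missing = [u for u in unit_ids if u not in order.index]
        if missing:
            raise ValueError(f"{path}: no label for unit {missing[0]}")
        labels = labels.to_numpy()[order.loc[list(unit_ids)].to_numpy()]
        ids = pd.Series(list(unit_ids))
    return Partition(np.asarray(labels), unit_ids=list(ids))


def write_partition(part: Partition, path, unit_ids=None) -> None:
    ids = unit_ids or part.unit_ids or [f"U{i + 1}" for i in range(part.n)]
    pd.DataFrame({"id": ids, "label": part.labels}).to_csv(
        path, sep=_sep(path), index=False
    )


def read_partition_matrix(path) -> tuple[np.ndarray, list]:
    """Read a wide partition file: one id column then one label column per
    partition.  Returns (n x n_partitions label array, unit ids)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return df.to_numpy(dtype=int), list(df.index.astype(str))


def read_mixed_table(path, kinds_path) -> MixedDataTable:
    """Read a units-by-variables table plus its variable-kind declaration.

    The side-car file has two columns (variable name, kind) with kinds in
    {continuous, binary, qualitative}.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0, dtype=object)
    kinds_df = pd.read_csv(kinds_path, sep=_sep(kinds_path))
    if kinds_df.shape[1] < 2:
        raise ValueError(f"{kinds_path}: expected two columns (variable, kind)")
    kinds = dict(
        zip(kinds_df.iloc[:, 0].astype(str), kinds_df.iloc[:, 1].astype(str))
    )
    missing = [c for c in df.columns if c not in kinds]
    if missing:
        raise ValueError(f"{kinds_path}: no kind declared for variable {missing[0]}")
    bad = {c: kinds[c] for c in df.columns if kinds[c] not in VAR_KINDS}
    if bad:
        c, k = next(iter(bad.items()))
        raise ValueError(f"{kinds_path}: variable {c} has unknown kind {k!r}")
    # numeric conversion for continuous/binary columns (missing stays NaN)
    conv = df.copy()
    for c in df.columns:
        if kinds[c] in ("continuous", "binary"):
            conv[c] = pd.to_numeric(df[c], errors="coerce")
    return MixedDataTable.from_frame(conv, {c: kinds[c] for c in df.columns})


def read_test_distances(path, unit_ids=None) -> np.ndarray:
    """Read the distances from a candidate unit to the n reference units
    (one- or two-column file; with two columns the first holds unit ids
    aligned to ``unit_ids`` when given)."""
    df = pd.read_csv(path, sep=_sep(path))
    if df.shape[1] == 1:
        return df.iloc[:, 0].to_numpy(dtype=float)
    ids = df.iloc[:, 0].astype(str)
    vals = df.iloc[:, 1].to_numpy(dtype=float)
    if unit_ids is not None:
        order = pd.Series(np.arange(len(ids)), index=ids)
        missing = [u for u in unit_ids if u not in order.index]
        if missing:
            raise ValueError(f"{path}: no distance for unit {missing[0]}")
        vals = vals[order.loc[list(unit_ids)].to_numpy()]
    return vals


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.integer):
            return int(o)
        if isinstance(o, np.floating):
            return float(o)
        if isinstance(o, np.bool_):
            return bool(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder) + "\n")
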