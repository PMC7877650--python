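"""Multipoint Morisita index, intrinsic dimension, redundancy reduction.

The m-point Morisita index measures how often m points co-occur in the cells
of a regular grid, relative to the expectation under randomness:

    I_{m,delta} = Q^{m-1} * sum_i n_i (n_i-1) ... (n_i-m+1)
                           / [N (N-1) ... (N-m+1)]

where the data (min-max scaled to the unit hypercube) are gridded with cells
of edge ``delta``, ``n_i`` is the count in cell i and ``Q`` the total number
of cells.  I ≈ 1 for random patterns, > 1 for clustered and < 1 for regular
(structured) ones.

Across scales, ``log I_{m,delta}`` is linear in ``log delta`` with slope
``S_m = (m-1)(D_m - E)`` for data of (Rényi) dimension ``D_m`` embedded in
E features, which yields the Morisita-based intrinsic dimension estimate

    ID = E + S_m / (m - 1).

For uniform data filling all E dimensions the index is flat in delta and
ID = E; redundant (e.g. duplicated) features lower ID below E.  Greedy
forward selection maximising the ID of the selected subset ranks features by
the new, non-redundant information they add (Morisita-based redundancy
reduction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lgc import FeatureMatrix
from .fractal import fit_loglog

__all__ = [
    "MorisitaCurve",
    "IDEstimate",
    "FeatureRanking",
    "morisita_index",
    "estimate_id",
    "rank_redundancy",
    "grid_cell_counts",
]


def _as_array(data) -> np.ndarray:
    if isinstance(data, FeatureMatrix):
        data = data.values
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    return X


def _minmax_unit(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span = np.where(span > 0, span, 1.0)  # constant feature -> all zeros
    return (X - lo) / span


def grid_cell_counts(X01: np.ndarray, delta: float) -> np.ndarray:
    """Occupied-cell point counts for a grid of edge ``delta`` on [0,1]^E.

    Cells are half-open with the last cell closed: a point exactly on the
    upper domain boundary belongs to the last cell.
    """
    q_ax = int(round(1.0 / delta))
    if q_ax < 1:
        raise ValueError("delta must be <= 1")
    idx = np.minimum((X01 / delta).astype(np.int64), q_ax - 1)
    _, counts = np.unique(idx, axis=0, return_counts=True)
    return counts


def _falling_factorial_log(n: float, m: int) -> float:
    """log of n(n-1)...(n-m+1) for scalar n >= m."""
    return float(np.sum(np.log(n - np.arange(m))))


@dataclass(frozen=True)
class MorisitaCurve:
    """I_{m,delta} across cell sizes, with per-cell counts kept for audit."""

    m: int
    deltas: np.ndarray
    Q: np.ndarray                 # total cells per delta
    values: np.ndarray            # I_{m,delta}
    cell_counts: list             # occupied-cell counts n_i per delta
    E: int


def morisita_index(data, m: int = 2, deltas=None, rescale: bool = True) -> MorisitaCurve:
    """Multipoint Morisita index of *data* across grid resolutions.

    Features are min-max scaled to [0,1] before gridding (pass
    ``rescale=False`` for data already expressed in the unit hypercube).
    The default delta grid is dyadic: 1/2, 1/4, ..., 1/32.
    """
    X = _as_array(data)
    n, E = X.shape
    if m < 2:
        raise ValueError("index order m must be >= 2")
    if n < m:
        raise ValueError(f"need at least m={m} points")
    if deltas is None:
        deltas = 1.0 / 2.0 ** np.arange(1, 6)
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        raise ValueError("empty delta list")
    if rescale:
        X01 = _minmax_unit(X)
    else:
        if X.min() < 0 or X.max() > 1:
            raise ValueError("rescale=False requires data inside the unit hypercube")
        X01 = X
    log_ffN = _falling_factorial_log(n, m)
    values = np.empty(deltas.size)
    Qs = np.empty(deltas.size)
    all_counts = []
    for j, delta in enumerate(deltas):
        counts = grid_cell_counts(X01, delta)
        all_counts.append(counts)
        q_ax = int(round(1.0 / delta))
        logQ = E * np.log(q_ax)
        Qs[j] = float(q_ax) ** E
        big = counts[counts >= m].astype(float)
        if big.size == 0:
            values[j] = 0.0
            continue
        # sum of per-cell falling factorials, evaluated in log space: Q^{m-1}
        # can exceed 1e30 for fine grids in high E while the ratio stays O(1)
        term = np.zeros(big.size)
        for i in range(m):
            term += np.log(big - i)
        values[j] = float(np.sum(np.exp(term + (m - 1) * logQ - log_ffN)))
    return MorisitaCurve(m, deltas, Qs, values, all_counts, E)


@dataclass(frozen=True)
class IDEstimate:
    """Morisita-based intrinsic dimension of a feature matrix."""

    id_value: float
    E: int
    slope: float
    m: int
    delta_range: tuple


def estimate_id(data, m: int = 2, deltas=None, min_points_per_cell: float | None = None) -> IDEstimate:
    """Intrinsic dimension from the log-log slope of the Morisita curve.

    Deltas where the index is zero are dropped.  Among the two finest
    scales, deltas where the mean count per occupied cell falls below m are
    also dropped: at that occupancy the m-tuple counts are dominated by
    Poisson noise.  At least three usable deltas are required.
    """
    curve = morisita_index(data, m=m, deltas=deltas)
    usable = curve.values > 0
    thresh = float(m) if min_points_per_cell is None else min_points_per_cell
    fine = np.argsort(curve.deltas)[:2]  # two smallest deltas
    for j in fine:
        if usable[j]:
            counts = curve.cell_counts[j]
            if counts.mean() < thresh:
                usable[j] = False
    if usable.sum() < 3:
        raise ValueError(
            f"only {int(usable.sum())} usable delta(s); need >= 3 "
            "(increase n or coarsen the delta grid)"
        )
    fit = fit_loglog(curve.deltas, curve.values, mask=usable)
    dr = (float(curve.deltas[usable].min()), float(curve.deltas[usable].max()))
    id_value = curve.E + fit.slope / (m - 1)
    return IDEstimate(float(id_value), curve.E, fit.slope, m, dr)


@dataclass(frozen=True)
class FeatureRanking:
    """Greedy Morisita-ID feature ranking (redundancy reduction)."""

    order: list
    id_trace: list
    selected: list
    threshold: float


def rank_redundancy(features, m: int = 2, threshold: float = 0.05, deltas=None) -> FeatureRanking:
    """Rank features by their contribution to the intrinsic dimension.

    Greedy forward selection: at every step add the feature whose inclusion
    maximises the Morisita ID of the selected subset (ties broken by lowest
    feature index).  Features stop entering ``selected`` once the best ID
    gain drops below ``threshold``; the full ranking ``order`` is still
    reported for diagnostics.
    """
    if isinstance(features, FeatureMatrix):
        X = features.values
        names = list(features.feature_names)
    else:
        X = _as_array(features)
        names = [f"f{i + 1}" for i in range(X.shape[1])]
    p = X.shape[1]
    if p < 1:
        raise ValueError("need at least one feature")

    def subset_id(cols) -> float:
        try:
            return estimate_id(X[:, cols], m=m, deltas=deltas).id_value
        except ValueError:
            return -np.inf

    remaining = list(range(p))
    chosen: list[int] = []
    order: list[str] = []
    trace: list[float] = []
    selected: list[str] = []
    prev_id = 0.0
    selecting = True
    while remaining:
        ids = [subset_id(chosen + [c]) for c in remaining]
        best_pos = int(np.argmax(ids))  # first max -> lowest feature index
        best_id = ids[best_pos]
        col = remaining.pop(best_pos)
        chosen.append(col)
        order.append(names[col])
        trace.append(float(best_id))
        if selecting and np.isfinite(best_id) and best_id - prev_id >= threshold:
            selected.append(names[col])
            prev_id = best_id
        else:
            selecting = False
    return FeatureRanking(order, trace, selected, threshold)
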