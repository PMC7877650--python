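"""Global fractal-dimension estimators for planar point patterns.

Two standard estimators are provided:

* **Box counting** — cover the pattern's bounding box with a regular grid of
  cell edge ``l`` and count occupied cells ``N(l)``.  For a fractal support,
  ``N(l) ~ l^(-fb)``; the box dimension ``fb`` is minus the slope of
  ``log N`` against ``log l``.

* **Sandbox counting** — centre a disc of radius ``R`` on every point and
  count the *other* points inside (closed ball, centre excluded); average the
  counts over all centres.  For a fractal pattern ``<N(R)> ~ R^f_sb``; the
  sandbox dimension is the slope of ``log <N>`` against ``log R``.  This is
  the global average of the local growth curves and is closely related to
  Ripley's K function and the Grassberger–Procaccia correlation dimension.

Neither estimator applies edge corrections: the intended workflow compares
an observed pattern to a CSR reference simulated in the same validity
domain, so boundary effects cancel in the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "RadiusGrid",
    "LogLogFit",
    "BoxCountCurve",
    "SandboxCurve",
    "make_radius_grid",
    "fit_loglog",
    "box_count",
    "sandbox_count",
]


@dataclass(frozen=True)
class RadiusGrid:
    """Strictly increasing grid of positive radii (length units)."""

    radii: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        object.__setattr__(self, "radii", r)
        if r.ndim != 1 or r.size < 2:
            raise ValueError("need at least two radii")
        if not np.all(r > 0):
            raise ValueError("radii must be positive")
        if not np.all(np.diff(r) > 0):
            raise ValueError("radii must be strictly increasing")

    @property
    def d(self) -> int:
        return self.radii.size

    def nearest_index(self, r: float) -> int:
        return int(np.argmin(np.abs(self.radii - r)))


def make_radius_grid(r_min: float, r_max: float, d: int = 25, spacing: str = "geometric") -> RadiusGrid:
    """Radius grid with both endpoints included; geometric spacing default."""
    if not (0 < r_min < r_max):
        raise ValueError("need 0 < r_min < r_max")
    if d < 2:
        raise ValueError("need d >= 2")
    if spacing == "geometric":
        return RadiusGrid(np.geomspace(r_min, r_max, d))
    if spacing == "linear":
        return RadiusGrid(np.linspace(r_min, r_max, d))
    raise ValueError(f"unknown spacing {spacing!r}")


@dataclass(frozen=True)
class LogLogFit:
    """OLS fit of log(value) on log(scale), restricted to positive values."""

    slope: float
    intercept: float
    r_squared: float
    used_mask: np.ndarray


def fit_loglog(scales, values, mask=None) -> LogLogFit:
    """Least-squares slope of ``ln values`` against ``ln scales``.

    Pairs with non-positive values are dropped (recorded in ``used_mask``);
    at least two usable pairs are required.  Exact on perfect power laws.
    ``r_squared`` is NaN when fewer than three points enter the fit, or when
    the response is constant (zero total variance).
    """
    scales = np.asarray(scales, dtype=float)
    values = np.asarray(values, dtype=float)
    if scales.shape != values.shape:
        raise ValueError("scales and values must have equal length")
    used = np.isfinite(values) & (values > 0) & np.isfinite(scales) & (scales > 0)
    if mask is not None:
        used = used & np.asarray(mask, dtype=bool)
    if used.sum() < 2:
        raise ValueError("need at least two pairs with positive values to fit")
    x = np.log(scales[used])
    y = np.log(values[used])
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        raise ValueError("all usable scales identical; slope undefined")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    syy = float(((y - y.mean()) ** 2).sum())
    if used.sum() < 3 or syy == 0:
        r2 = float("nan")
    else:
        r2 = 1.0 - float((resid @ resid)) / syy
    return LogLogFit(slope, intercept, r2, used)


@dataclass(frozen=True)
class BoxCountCurve:
    scales: np.ndarray       # cell edge lengths l
    counts: np.ndarray       # occupied-cell counts N(l)
    fit: LogLogFit

    @property
    def dimension(self) -> float:
        """Box-counting dimension fb = -slope of log N(l) vs log l."""
        return -self.fit.slope


@dataclass(frozen=True)
class SandboxCurve:
    radii: RadiusGrid
    mean_counts: np.ndarray  # <N(R)>, centre excluded
    fit: LogLogFit

    @property
    def dimension(self) -> float:
        """Sandbox dimension f_sb = slope of log <N(R)> vs log R."""
        return self.fit.slope


def _default_box_scales(pattern, n_scales: int = 12) -> np.ndarray:
    xmin, ymin, xmax, ymax = pattern.bbox
    side = max(xmax - xmin, ymax - ymin)
    if side <= 0:  # all points coincide
        side = 1.0
    return side / 2.0 ** np.arange(1, n_scales + 1)


def box_count(pattern, scales=None, min_points_per_cell: float = 10.0) -> BoxCountCurve:
    """Occupied-cell counts over a grid of cell sizes, with a log-log fit.

    The grid at each scale is anchored at the bounding-box minimum corner.
    The fit excludes saturated scales (``N(l) <= 1``, or all points isolated)
    and undersampled scales where the mean number of points per occupied cell
    drops below ``min_points_per_cell``: below that occupancy the pattern is
    resolved into individual points and the count flattens toward ``n``,
    which would bias the slope low.  If the guards leave fewer than two
    scales they are relaxed (undersampling guard first).
    """
    coords = pattern.coords
    n = coords.shape[0]
    if n < 1:
        raise ValueError("empty pattern")
    if scales is None:
        scales = _default_box_scales(pattern)
    scales = np.sort(np.asarray(scales, dtype=float))[::-1]
    if np.any(scales <= 0):
        raise ValueError("scales must be positive")
    xmin, ymin, xmax, ymax = pattern.bbox
    rel = coords - np.array([xmin, ymin])
    span = np.array([max(xmax - xmin, 1e-300), max(ymax - ymin, 1e-300)])
    counts = np.empty(scales.size, dtype=np.int64)
    for i, l in enumerate(scales):
        ncells = np.maximum(np.ceil(span / l), 1).astype(np.int64)
        # points exactly on the far edge fall into the last cell
        ij = np.minimum(np.floor(rel / l).astype(np.int64), ncells - 1)
        counts[i] = np.unique(ij[:, 0] + (ij[:, 1] << 32)).size
    fit = _guarded_fit(scales, counts.astype(float), n, min_points_per_cell)
    return BoxCountCurve(scales, counts, fit)


def _guarded_fit(scales, counts, n, min_points_per_cell):
    not_saturated = counts > 1
    well_sampled = counts * min_points_per_cell <= n
    for mask in (not_saturated & well_sampled, not_saturated, np.ones_like(not_saturated)):
        if (mask & (counts > 0)).sum() >= 2:
            return fit_loglog(scales, counts, mask=mask)
    # single point: N(l) = 1 everywhere, dimension 0 by convention
    return LogLogFit(0.0, 0.0, float("nan"), counts > 0)


def sandbox_count(pattern, radii: RadiusGrid) -> SandboxCurve:
    """Mean number of other points within R of each point, per radius.

    Uses KD-tree pair counting: ``count_neighbors`` returns the number of
    ordered pairs within distance R including self-pairs, so the mean
    per-centre count of *other* points is ``pairs/n - 1``.
    """
    coords = pattern.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("sandbox counting needs at least two points")
    tree = cKDTree(coords)
    pairs = tree.count_neighbors(tree, radii.radii)
    mean_counts = pairs.astype(float) / n - 1.0
    try:
        fit = fit_loglog(radii.radii, mean_counts)
    except ValueError:
        # fewer than two radii see any neighbour: counts reported, no slope
        fit = LogLogFit(float("nan"), float("nan"), float("nan"), mean_counts > 0)
    return SandboxCurve(radii, mean_counts, fit)
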