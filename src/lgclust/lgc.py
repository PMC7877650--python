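"""Local growth curves: the per-point feature embedding.

The local growth curve (LGC) of a point is the vector ``N(R_1) ... N(R_d)``
of *other*-point counts within increasing radii — the un-averaged version of
the sandbox statistic.  Stacking the curves of all n points gives an n × d
feature matrix in which each point is described by its local density across
d spatial scales.  The per-point log-log slope of the curve is (loosely) a
local fractal dimension, which together with the local density at a fixed
radius drives the interpretation of clustering results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .fractal import RadiusGrid

__all__ = [
    "GrowthCurveMatrix",
    "LocalDimensionField",
    "FeatureMatrix",
    "PCASummary",
    "build_lgc",
    "local_fdim",
    "preprocess",
    "pca_summary",
]


@dataclass(frozen=True)
class GrowthCurveMatrix:
    """n × d matrix of local growth curves; entry (j, i) counts the other
    points within radius R_i of point j (closed ball, centre excluded)."""

    counts: np.ndarray
    radii: RadiusGrid
    point_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (self.point_ids.size, self.radii.d):
            raise ValueError("counts shape must be (n_points, n_radii)")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_curve(self) -> np.ndarray:
        """Column means; identical to the sandbox mean counts."""
        return self.counts.mean(axis=0)

    @property
    def feature_names(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.radii.d)]


@dataclass(frozen=True)
class LocalDimensionField:
    """Per-point local fractal dimensions with a validity mask.

    ``fdim[j]`` is the OLS slope of ``log N(R)`` vs ``log R`` over the radii
    where point j sees at least one neighbour; points with fewer than three
    usable radii are flagged invalid (``fdim`` NaN there, never silently 0).
    """

    fdim: np.ndarray
    valid: np.ndarray

    @property
    def values(self) -> np.ndarray:
        """The finite dimensions only (invalid points dropped)."""
        return self.fdim[self.valid]


def build_lgc(pattern, radii: RadiusGrid) -> GrowthCurveMatrix:
    """Count, for every point and radius, the other points within reach."""
    coords = pattern.coords
    n = coords.shape[0]
    if n < 2:
        raise ValueError("local growth curves need at least two points")
    tree = cKDTree(coords)
    counts = np.empty((n, radii.d), dtype=np.int64)
    for i, r in enumerate(radii.radii):
        counts[:, i] = tree.query_ball_point(coords, r, return_length=True)
    counts -= 1  # remove the centre point itself
    return GrowthCurveMatrix(counts, radii, np.arange(n))


def local_fdim(lgc: GrowthCurveMatrix, min_radii: int = 3) -> LocalDimensionField:
    """Per-point log-log slope of the growth curve (local fractal dimension).

    Radii with zero counts are dropped from each point's fit (no +1 offset:
    an offset would bias the slope at small radii).  The masking policy
    matches the global sandbox fit so local and global dimensions are
    comparable.
    """
    counts = lgc.counts
    x = np.log(lgc.radii.radii)[None, :]
    mask = counts >= 1
    k = mask.sum(axis=1)
    valid = k >= min_radii
    with np.errstate(divide="ignore", invalid="ignore"):
        y = np.where(mask, np.log(np.maximum(counts, 1)), 0.0)
        xm = np.where(mask, x, 0.0)
        sx = xm.sum(axis=1)
        sy = y.sum(axis=1)
        sxx = (xm * xm).sum(axis=1)
        sxy = (xm * y).sum(axis=1)
        kf = np.maximum(k, 1).astype(float)
        denom = sxx - sx * sx / kf
        slope = np.where(denom > 0, (sxy - sx * sy / kf) / np.where(denom > 0, denom, 1.0), np.nan)
    fdim = np.where(valid, slope, np.nan)
    return LocalDimensionField(fdim, valid)


@dataclass(frozen=True)
class FeatureMatrix:
    """Preprocessed n × p feature matrix ready for clustering."""

    values: np.ndarray
    transform: str
    feature_names: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("one name per feature column required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, names) -> "FeatureMatrix":
        idx = [self.feature_names.index(nm) for nm in names]
        return FeatureMatrix(self.values[:, idx], self.transform, [self.feature_names[i] for i in idx])

    @classmethod
    def from_array(cls, values, feature_names=None, transform="raw") -> "FeatureMatrix":
        values = np.asarray(values, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        names = feature_names or [f"f{i + 1}" for i in range(values.shape[1])]
        return cls(values, transform, list(names))


TRANSFORMS = ("raw", "log1p", "zscore", "log1p+zscore")


def preprocess(lgc: GrowthCurveMatrix, transform: str = "log1p+zscore") -> FeatureMatrix:
    """Turn raw growth-curve counts into a clustering feature matrix.

    ``log1p`` compresses counts spanning orders of magnitude; ``zscore``
    standardises each radius column so no single scale dominates Euclidean
    distances.  Zero-variance columns are dropped under z-scoring (with a
    warning) since they carry no information and would divide by zero.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")
    X = lgc.counts.astype(float)
    names = lgc.feature_names
    if "log1p" in transform:
        X = np.log1p(X)
    if "zscore" in transform:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 0
        if not keep.all():
            dropped = [names[i] for i in np.where(~keep)[0]]
            warnings.warn(f"dropping zero-variance feature column(s): {dropped}")
            X, mu, sd = X[:, keep], mu[keep], sd[keep]
            names = [nm for nm, k in zip(names, keep) if k]
        X = (X - mu) / sd
    return FeatureMatrix(X, transform, list(names))


@dataclass(frozen=True)
class PCASummary:
    """Variance fractions of the principal components of a feature matrix."""

    explained_fraction: np.ndarray

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained_fraction)

    def n_components(self, coverage: float = 0.95) -> int:
        """Smallest number of components explaining at least *coverage*."""
        return int(np.searchsorted(self.cumulative, coverage) + 1)


def pca_summary(features: FeatureMatrix) -> PCASummary:
    """Explained-variance fractions from the covariance eigendecomposition.

    Rank-deficient inputs are fine: redundant features simply produce
    trailing zero-variance components — which is exactly the redundancy
    signal this summary is meant to expose.
    """
    X = features.values
    n, p = X.shape
    if p < 2:
        raise ValueError("PCA summary needs at least two features")
    if n <= p:
        raise ValueError("need more observations than features")
    cov = np.cov(X, rowvar=False)
    eig = np.linalg.eigvalsh(cov)[::-1]
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    if total == 0:
        raise ValueError("all features are constant")
    return PCASummary(eig / total)
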