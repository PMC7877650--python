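"""Synthetic point-pattern fixtures with known ground truth.

These generators provide the controlled inputs for validating the fractal
estimators and the clustering pipeline: CSR for the homogeneous reference
(dimension 2 in the plane), a line for dimension 1, the Sierpinski triangle
for a known fractal dimension log 3 / log 2, Gaussian blobs and Thomas
cluster processes for labelled clustered patterns, and a regular lattice
for structured (anti-clustered) patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domain import PointPattern, ValidityDomain, generate_csr

__all__ = ["SyntheticSpec", "generate_fixture"]

KINDS = ("csr", "blobs", "thomas", "sierpinski", "line", "grid")

# Default blob layout: three compact clusters with distinct spreads and
# *unequal* pairwise separations (~3350 / 5190 / 6900 length units).  Each
# neighbouring blob enters a point's growth curve at a different radius, so
# every cluster has a unique staircase signature across radii — emulating
# settlements of different compactness at unequal spacings.  The spreads are
# small relative to the separations, keeping the staircase steps sharp and
# the ground-truth feature-space structure unambiguous.  Units are arbitrary
# metric lengths.
_BLOB_CENTERS = ((0.0, 0.0), (3350.0, 0.0), (4761.0, 4995.0))
_BLOB_SDS = (10.0, 20.0, 40.0)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic pattern: kind, size, parameters, seed."""

    kind: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def generate_fixture(spec: SyntheticSpec) -> PointPattern:
    """Generate the pattern described by *spec*; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    n = spec.n
    if spec.kind == "csr":
        domain = p.get("domain") or ValidityDomain.box(0.0, 0.0, 1.0, 1.0)
        return generate_csr(domain, n, spec.seed)
    if spec.kind == "blobs":
        return _blobs(
            n,
            rng,
            centers=np.asarray(p.get("centers", _BLOB_CENTERS), dtype=float),
            sds=np.asarray(p.get("sds", _BLOB_SDS), dtype=float),
        )
    if spec.kind == "thomas":
        return _thomas(
            n,
            rng,
            n_parents=int(p.get("n_parents", 25)),
            sd=float(p.get("sd", 0.02)),
            extent=float(p.get("extent", 1.0)),
        )
    if spec.kind == "sierpinski":
        return _sierpinski(n, rng, side=float(p.get("side", 1.0)))
    if spec.kind == "line":
        return _line(n, length=float(p.get("length", 1.0)))
    if spec.kind == "grid":
        return _grid(n, extent=float(p.get("extent", 1.0)))
    raise ValueError(f"unknown fixture kind {spec.kind!r}")  # pragma: no cover


def _blobs(n: int, rng: np.random.Generator, centers: np.ndarray, sds: np.ndarray) -> PointPattern:
    """k isotropic Gaussian clusters with ground-truth labels."""
    k = len(centers)
    if len(sds) != k:
        raise ValueError("need one spread per centre")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    parts, labels = [], []
    for j in range(k):
        parts.append(centers[j] + sds[j] * rng.standard_normal((sizes[j], 2)))
        labels.append(np.full(sizes[j], j))
    return PointPattern(np.vstack(parts), labels=np.concatenate(labels))


def _thomas(n: int, rng: np.random.Generator, n_parents: int, sd: float, extent: float) -> PointPattern:
    """Thomas cluster process: Poisson parents, Gaussian offspring, fixed n."""
    n_par = max(1, rng.poisson(n_parents))
    parents = rng.uniform(0, extent, (n_par, 2))
    which = rng.integers(0, n_par, n)
    pts = parents[which] + sd * rng.standard_normal((n, 2))
    return PointPattern(pts, labels=which)


def _sierpinski(n: int, rng: np.random.Generator, side: float) -> PointPattern:
    """Chaos-game sample of the Sierpinski triangle (dimension log3/log2)."""
    verts = side * np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
    burn = 32
    choice = rng.integers(0, 3, n + burn)
    pts = np.empty((n + burn, 2))
    x = rng.uniform(0, side, 2)
    for i, c in enumerate(choice):
        x = 0.5 * (x + verts[c])
        pts[i] = x
    return PointPattern(pts[burn:])


def _line(n: int, length: float) -> PointPattern:
    """Evenly spaced points on a horizontal segment (dimension 1)."""
    x = np.linspace(0.0, length, n)
    return PointPattern(np.column_stack([x, np.zeros(n)]))


def _grid(n: int, extent: float) -> PointPattern:
    """Regular lattice of ~n points filling a square (structured pattern)."""
    side = int(np.ceil(np.sqrt(n)))
    ax = np.linspace(0.0, extent, side)
    xx, yy = np.meshgrid(ax, ax)
    pts = np.column_stack([xx.ravel(), yy.ravel()])[:n]
    return PointPattern(pts)
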