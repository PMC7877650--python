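"""Validity-domain geometry, point patterns and CSR simulation.

A *validity domain* is the region where the studied phenomenon can exist
(e.g. a national border minus its lakes): every point pattern is conditioned
on it, and complete-spatial-randomness (CSR) reference patterns are simulated
inside it rather than inside a bounding rectangle.  Comparing an observed
pattern against CSR *in the same domain* separates genuine clustering from
the "natural clustering" imposed by the domain shape.

Coordinates are planar and metric (any consistent length unit).  Geographic
longitude/latitude is rejected: all distances here are Euclidean, so data
must be projected first.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Polygon, mapping, shape

__all__ = [
    "ValidityDomain",
    "PointPattern",
    "read_domain",
    "write_domain",
    "read_points",
    "write_points",
    "generate_csr",
]

_GEOGRAPHIC_UNITS = {"deg", "degree", "degrees", "lonlat", "latlon", "wgs84"}


@dataclass(frozen=True)
class ValidityDomain:
    """Polygon-with-holes region where points may exist.

    Parameters
    ----------
    geometry : shapely Polygon or MultiPolygon
        Outer ring(s) with optional interior rings (holes).  Boundary points
        count as inside (closed-set convention): gridded cell centres may lie
        exactly on a border.
    """

    geometry: Polygon | MultiPolygon

    def __post_init__(self) -> None:
        geom = self.geometry
        if not isinstance(geom, (Polygon, MultiPolygon)):
            raise TypeError(f"expected Polygon or MultiPolygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise ValueError("domain geometry is invalid (self-intersecting rings?)")
        if geom.area <= 0:
            raise ValueError("domain area must be positive")

    @property
    def polygons(self) -> list[Polygon]:
        g = self.geometry
        return [g] if isinstance(g, Polygon) else list(g.geoms)

    @property
    def outer_rings(self) -> list[np.ndarray]:
        return [np.asarray(p.exterior.coords) for p in self.polygons]

    @property
    def holes(self) -> list[np.ndarray]:
        return [np.asarray(r.coords) for p in self.polygons for r in p.interiors]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        return self.geometry.bounds

    @property
    def area(self) -> float:
        return self.geometry.area

    def contains(self, point) -> bool:
        """True iff *point* lies in an outer ring and outside all holes.

        Boundary points count as inside.
        """
        x, y = float(point[0]), float(point[1])
        if not (np.isfinite(x) and np.isfinite(y)):
            raise ValueError("point coordinates must be finite")
        return bool(shapely.covers(self.geometry, shapely.points(x, y)))

    def contains_many(self, coords: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`contains` for an (n, 2) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        pts = shapely.points(coords[:, 0], coords[:, 1])
        return shapely.covers(self.geometry, pts)

    @classmethod
    def from_rings(cls, outer, holes=()) -> "ValidityDomain":
        """Build from one outer ring and optional hole rings (vertex lists)."""
        return cls(Polygon(outer, holes=[list(h) for h in holes]))

    @classmethod
    def box(cls, xmin: float, ymin: float, xmax: float, ymax: float) -> "ValidityDomain":
        return cls(shapely.box(xmin, ymin, xmax, ymax))


@dataclass
class PointPattern:
    """A planar spatial point pattern with metric coordinates.

    ``labels`` carries ground-truth group labels for synthetic fixtures and
    is ``None`` for observed data.
    """

    coords: np.ndarray
    units: str = "m"
    domain: ValidityDomain | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError(f"coords must be (n, 2), got {self.coords.shape}")
        if self.coords.shape[0] < 1:
            raise ValueError("a point pattern needs at least one point")
        if not np.all(np.isfinite(self.coords)):
            bad = np.where(~np.isfinite(self.coords).all(axis=1))[0]
            raise ValueError(f"non-finite coordinates at rows {bad[:10].tolist()}")
        if self.units.lower() in _GEOGRAPHIC_UNITS:
            raise ValueError(
                "geographic lon/lat coordinates are not supported: distances are "
                "Euclidean, pre-project to a planar metric CRS first"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.n:
                raise ValueError("labels length must match number of points")
        if self.domain is not None:
            inside = self.domain.contains_many(self.coords)
            if not inside.all():
                raise ValueError(
                    f"{int((~inside).sum())} point(s) fall outside the validity domain"
                )

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def bbox(self) -> tuple[float, float, float, float]:
        xmin, ymin = self.coords.min(axis=0)
        xmax, ymax = self.coords.max(axis=0)
        return float(xmin), float(ymin), float(xmax), float(ymax)


def generate_csr(domain: ValidityDomain, n: int, seed: int) -> PointPattern:
    """Simulate complete spatial randomness inside a validity domain.

    Points are i.i.d. uniform over the domain, drawn by rejection sampling
    from the bounding box; this is exact for arbitrary hole geometry.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xmin, ymin, xmax, ymax = domain.bbox
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("degenerate bounding box")
    frac = domain.area / ((xmax - xmin) * (ymax - ymin))
    if frac <= 0:
        raise ValueError("domain area must be positive")
    rng = np.random.default_rng(seed)
    shapely.prepare(domain.geometry)  # in-place spatial index for covers()
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(1024, int(1.2 * (n - filled) / frac))
        cand = np.column_stack(
            [rng.uniform(xmin, xmax, m), rng.uniform(ymin, ymax, m)]
        )
        keep = shapely.covers(domain.geometry, shapely.points(cand[:, 0], cand[:, 1]))
        cand = cand[keep]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return PointPattern(out, domain=domain)


# ---------------------------------------------------------------------------
# I/O: GeoJSON domains, CSV point tables
# ---------------------------------------------------------------------------

def read_domain(path) -> ValidityDomain:
    """Read a validity domain from a GeoJSON file (RFC 7946).

    Accepts a bare geometry, a Feature or a FeatureCollection whose
    geometries are Polygon/MultiPolygon; multiple features are unioned.
    """
    with open(path) as fh:
        try:
            obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{path}: not valid JSON/GeoJSON: {exc}") from exc
    geoms = []
    t = obj.get("type")
    if t == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in obj.get("features", [])]
    elif t == "Feature":
        geoms = [shape(obj["geometry"])]
    elif t in ("Polygon", "MultiPolygon"):
        geoms = [shape(obj)]
    else:
        raise ValueError(f"{path}: unsupported GeoJSON type {t!r}")
    if not geoms:
        raise ValueError(f"{path}: no geometry found")
    for g in geoms:
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValueError(f"{path}: geometry type {g.geom_type} is not a polygon")
    merged = geoms[0] if len(geoms) == 1 else shapely.union_all(geoms)
    return ValidityDomain(merged)


def write_domain(domain: ValidityDomain, path) -> None:
    with open(path, "w") as fh:
        json.dump(mapping(domain.geometry), fh)


def read_points(path, units: str = "m", domain: ValidityDomain | None = None) -> PointPattern:
    """Read a point pattern from CSV with header columns ``x,y``.

    An optional ``label`` column is loaded as ground-truth labels.
    """
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty point table")
    missing = {"x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    bad = np.where(~np.isfinite(xy).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"{path}: non-finite coordinates at data row(s) {bad[:10].tolist()}")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return PointPattern(xy, units=units, domain=domain, labels=labels)


def write_points(pattern: PointPattern, path) -> None:
    """Write a point pattern as CSV; coordinates round-trip at full precision."""
    import pandas as pd

    data = {"x": pattern.coords[:, 0], "y": pattern.coords[:, 1]}
    if pattern.labels is not None:
        data["label"] = pattern.labels
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")
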