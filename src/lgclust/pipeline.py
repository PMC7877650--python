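"""End-to-end analysis pipeline and cluster interpretation.

Stages (in order): load or simulate a point pattern → build the local
growth curve (LGC) embedding → global fractal dimensions (box + sandbox) →
local fractal dimensions → Morisita intrinsic dimension and optional
redundancy reduction → clusterability (Hopkins) → number-of-clusters vote
(unless k is fixed) → clustering → per-cluster density/dimension profiling.
Every stage writes a CSV artifact and logs its parameters; the echoed
config plus the seed reproduce every artifact byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .clustering import (
    ClusterAssignment,
    clara,
    hierarchical,
    hopkins,
    kmeans,
    pam,
    som_cluster,
    vote_k,
)
from .domain import PointPattern, read_domain, read_points, write_points
from .fractal import box_count, make_radius_grid, sandbox_count
from .lgc import FeatureMatrix, GrowthCurveMatrix, LocalDimensionField, build_lgc, local_fdim, pca_summary, preprocess
from .morisita import estimate_id, rank_redundancy
from .som import som_train
from .synthesis import SyntheticSpec, generate_fixture

log = logging.getLogger("lgclust")

__all__ = ["RunConfig", "ClusterProfile", "run_pipeline", "profile_clusters", "compare_full_vs_reduced"]


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    points_csv: str | None = None
    domain_geojson: str | None = None
    synthetic: dict | None = None          # {"kind", "n", "params", "seed"} alternative to points_csv
    r_min: float = 300.0
    r_max: float = 10000.0
    n_radii: int = 25
    spacing: str = "geometric"
    transform: str = "log1p+zscore"
    method: str = "clara"                  # clara | pam | kmeans | som | hierarchical
    k: int | str = "vote"                  # integer or "vote"
    k_range: list = field(default_factory=lambda: list(range(2, 8)))
    redundancy: bool = False
    redundancy_threshold: float = 0.05
    morisita_m: int = 2
    profile_radius: float = 4000.0
    som_rows: int = 20
    som_cols: int = 15
    som_epochs: int = 30
    hier_subsample: int = 5000
    seed: int = 0
    outdir: str = "lgclust_run"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class ClusterProfile:
    """Per-cluster distributions of local density and local fractal dimension.

    Density is the LGC count at the grid radius nearest the requested
    profiling radius.  Histogram bins are shared across clusters
    (Freedman-Diaconis on the pooled data) so the distributions are
    directly comparable; per-cluster counts sum to the cluster size (minus
    reported invalid-dimension exclusions for the fDim histograms).
    """

    R_profile: float
    density_bins: np.ndarray
    density_hist: dict
    fdim_bins: np.ndarray
    fdim_hist: dict
    summary: pd.DataFrame
    n_invalid_fdim: int


def _shared_bins(values: np.ndarray, max_bins: int = 80) -> np.ndarray:
    values = values[np.isfinite(values)]
    edges = np.histogram_bin_edges(values, bins="fd")
    if edges.size - 1 > max_bins:
        edges = np.histogram_bin_edges(values, bins=max_bins)
    if edges.size < 2 or edges[0] == edges[-1]:
        edges = np.array([values.min() - 0.5, values.max() + 0.5])
    return edges


def profile_clusters(
    assignment: ClusterAssignment,
    lgc: GrowthCurveMatrix,
    fdim: LocalDimensionField,
    R_profile: float = 4000.0,
) -> ClusterProfile:
    """Density and local-dimension distributions for every cluster."""
    if assignment.labels.shape[0] != lgc.n or fdim.fdim.shape[0] != lgc.n:
        raise ValueError("assignment, LGC and fDim must describe the same points")
    radii = lgc.radii.radii
    if not (radii[0] <= R_profile <= radii[-1]):
        import warnings

        warnings.warn(
            f"profiling radius {R_profile} outside grid range "
            f"[{radii[0]}, {radii[-1]}]; snapping to nearest endpoint"
        )
    col = lgc.radii.nearest_index(R_profile)
    density = lgc.counts[:, col].astype(float)
    dbins = _shared_bins(density)
    fvals = fdim.fdim
    fbins = _shared_bins(fvals[fdim.valid]) if fdim.valid.any() else np.array([0.0, 1.0])
    dh, fh, rows = {}, {}, []
    for j in range(assignment.k):
        sel = assignment.labels == j
        dh[j] = np.histogram(density[sel], bins=dbins)[0]
        fsel = sel & fdim.valid
        fh[j] = np.histogram(fvals[fsel], bins=fbins)[0]
        rows.append(
            {
                "cluster": j,
                "size": int(sel.sum()),
                "density_mean": float(density[sel].mean()),
                "density_sd": float(density[sel].std()),
                "fdim_mean": float(fvals[fsel].mean()) if fsel.any() else np.nan,
                "fdim_sd": float(fvals[fsel].std()) if fsel.any() else np.nan,
            }
        )
    return ClusterProfile(
        float(radii[col]),
        dbins,
        dh,
        fbins,
        fh,
        pd.DataFrame(rows),
        int((~fdim.valid).sum()),
    )


def _cluster_with(method, features, k, config, rng_seed):
    if method == "kmeans":
        return kmeans(features, k, seed=rng_seed)
    if method == "pam":
        return pam(features, k, seed=rng_seed)
    if method == "clara":
        return clara(features, k, seed=rng_seed)
    if method == "som":
        model = som_train(
            features,
            rows=config.som_rows,
            cols=config.som_cols,
            epochs=config.som_epochs,
            seed=rng_seed,
        )
        return som_cluster(model, features, k, seed=rng_seed)
    if method == "hierarchical":
        X = features.values
        if X.shape[0] > config.hier_subsample:
            raise ValueError("hierarchical clustering needs n <= hier_subsample")
        return hierarchical(features).assignment(features, k)
    raise ValueError(f"unknown clustering method {method!r}")


def compare_full_vs_reduced(features: FeatureMatrix, config: RunConfig) -> dict:
    """Cluster on all features and on the redundancy-reduced subset.

    Returns the selected feature list, the ARI between the two assignments
    and the per-cluster size shift — a direct check that the reduced space
    preserves the clustering structure.
    """
    from sklearn.metrics import adjusted_rand_score

    ranking = rank_redundancy(
        features, m=config.morisita_m, threshold=config.redundancy_threshold
    )
    report: dict = {"selected": list(ranking.selected), "order": list(ranking.order)}
    if len(ranking.selected) < 2:
        import warnings

        warnings.warn("redundancy reduction selected < 2 features; comparison skipped")
        report["skipped"] = True
        return report
    k = config.k if isinstance(config.k, int) else vote_k(features, config.k_range, seed=config.seed).majority_k
    full = _cluster_with(config.method, features, k, config, config.seed)
    reduced = _cluster_with(config.method, features.subset(ranking.selected), k, config, config.seed)
    report["k"] = int(k)
    report["ari_full_vs_reduced"] = float(adjusted_rand_score(full.labels, reduced.labels))
    report["sizes_full"] = np.sort(full.sizes)[::-1].tolist()
    report["sizes_reduced"] = np.sort(reduced.sizes)[::-1].tolist()
    return report


def _stage(report, name, t0):
    dt = time.perf_counter() - t0
    log.info("stage %-14s done in %.2fs", name, dt)
    report.setdefault("stages", []).append({"name": name, "seconds": round(dt, 3)})
    return time.perf_counter()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run report (also written as YAML)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    report: dict = {"config": dataclasses.asdict(config)}
    t0 = time.perf_counter()

    # --- load -------------------------------------------------------------
    domain = read_domain(config.domain_geojson) if config.domain_geojson else None
    if config.points_csv:
        pattern = read_points(config.points_csv, domain=domain)
    elif config.synthetic:
        spec = SyntheticSpec(
            kind=config.synthetic["kind"],
            n=int(config.synthetic["n"]),
            params=config.synthetic.get("params", {}),
            seed=int(config.synthetic.get("seed", config.seed)),
        )
        pattern = generate_fixture(spec)
    else:
        raise ValueError("config must provide points_csv or synthetic")
    write_points(pattern, out / "points.csv")
    report["n_points"] = pattern.n
    t0 = _stage(report, "load", t0)

    # --- embedding --------------------------------------------------------
    radii = make_radius_grid(config.r_min, config.r_max, config.n_radii, config.spacing)
    lgc = build_lgc(pattern, radii)
    pd.DataFrame(lgc.counts, columns=lgc.feature_names).assign(point_id=lgc.point_ids).to_csv(
        out / "lgc.csv", index=False
    )
    t0 = _stage(report, "lgc", t0)

    # --- global fractal dimensions ----------------------------------------
    bc = box_count(pattern)
    sb = sandbox_count(pattern, radii)
    pd.DataFrame({"scale": bc.scales, "count": bc.counts, "used": bc.fit.used_mask}).to_csv(
        out / "boxcount.csv", index=False
    )
    pd.DataFrame(
        {"radius": radii.radii, "mean_count": sb.mean_counts, "used": sb.fit.used_mask}
    ).to_csv(out / "sandbox.csv", index=False)
    report["fdim_box"] = float(bc.dimension)
    report["fdim_sandbox"] = float(sb.dimension)
    t0 = _stage(report, "fractal", t0)

    # --- local dimensions ---------------------------------------------------
    fd = local_fdim(lgc)
    pd.DataFrame({"point_id": lgc.point_ids, "fdim": fd.fdim, "valid": fd.valid}).to_csv(
        out / "fdim.csv", index=False
    )
    report["fdim_local_mean"] = float(np.nanmean(fd.fdim)) if fd.valid.any() else None
    report["fdim_local_sd"] = float(np.nanstd(fd.fdim)) if fd.valid.any() else None
    t0 = _stage(report, "local_fdim", t0)

    # --- features, PCA, Morisita ID ----------------------------------------
    features = preprocess(lgc, config.transform)
    pca = pca_summary(features)
    report["pca_explained"] = pca.explained_fraction.round(6).tolist()
    try:
        ide = estimate_id(features, m=config.morisita_m)
        report["morisita_id"] = float(ide.id_value)
    except ValueError as exc:
        report["morisita_id"] = None
        log.warning("Morisita ID not estimable: %s", exc)
    if config.redundancy:
        report["redundancy"] = compare_full_vs_reduced(features, config)
    t0 = _stage(report, "morisita", t0)

    # --- clusterability and k ----------------------------------------------
    hop = hopkins(features, seed=config.seed)
    report["hopkins"] = {"statistic": hop.hopkins, "verdict": hop.verdict}
    if isinstance(config.k, int):
        k = config.k
    else:
        vote = vote_k(features, config.k_range, seed=config.seed)
        report["k_vote"] = {"votes": vote.index_votes, "majority_k": vote.majority_k}
        k = vote.majority_k
    report["k"] = int(k)
    t0 = _stage(report, "clusterability", t0)

    # --- clustering ---------------------------------------------------------
    assignment = _cluster_with(config.method, features, k, config, config.seed)
    pd.DataFrame(
        {
            "point_id": lgc.point_ids,
            "x": pattern.coords[:, 0],
            "y": pattern.coords[:, 1],
            "label": assignment.labels,
        }
    ).to_csv(out / "assignment.csv", index=False)
    report["cluster_sizes"] = assignment.sizes.tolist()
    t0 = _stage(report, "clustering", t0)

    # --- profiling ----------------------------------------------------------
    profile = profile_clusters(assignment, lgc, fd, config.profile_radius)
    profile.summary.to_csv(out / "profile.csv", index=False)
    report["profile"] = {
        "R_profile": profile.R_profile,
        "n_invalid_fdim": profile.n_invalid_fdim,
        "summary": profile.summary.to_dict(orient="records"),
    }
    _stage(report, "profiling", t0)

    with open(out / "report.yaml", "w") as fh:
        yaml.safe_dump(_yamlify(report), fh, sort_keys=False)
    return report


def _yamlify(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
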