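"""Self-organising (Kohonen) maps and SOM-based clustering.

A SOM is a 2-D grid of codebook vectors trained by the classical online
rule — competition (find the best-matching unit, BMU), cooperation (a
Gaussian neighbourhood around the BMU on the grid) and adaptation (move the
codebooks of the neighbourhood toward the sample).  After training, the
codebook is a topology-preserving quantisation of the data; clustering the
codebook (k-means or hierarchical) and mapping each sample through its BMU
yields a data clustering that is cheap even for large n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["SOMModel", "som_train", "som_quantization_error"]


def _grid_positions(rows: int, cols: int, topology: str) -> np.ndarray:
    """2-D positions of the grid nodes; hexagonal grids offset odd rows."""
    r, c = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    r = r.astype(float).ravel()
    c = c.astype(float).ravel()
    if topology == "hexagonal":
        c = c + 0.5 * (r.astype(int) % 2)
        r = r * (np.sqrt(3.0) / 2.0)
    elif topology != "rectangular":
        raise ValueError(f"unknown topology {topology!r}")
    return np.column_stack([r, c])


@dataclass
class SOMModel:
    """Trained map: grid shape/topology, codebook, per-epoch training log."""

    rows: int
    cols: int
    topology: str
    codebook: np.ndarray            # (rows*cols) x p
    training_log: list = field(default_factory=list)  # quantization error per epoch
    grid_positions: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.rows * self.cols

    def bmu(self, X: np.ndarray) -> np.ndarray:
        """Index of the best-matching unit for each row of X."""
        return np.argmin(cdist(np.atleast_2d(X), self.codebook, "sqeuclidean"), axis=1)


def som_quantization_error(model: SOMModel, X: np.ndarray) -> float:
    """Mean Euclidean distance from each sample to its BMU codebook."""
    d = cdist(X, model.codebook)
    return float(d.min(axis=1).mean())


def som_train(
    features,
    rows: int = 20,
    cols: int = 15,
    topology: str = "hexagonal",
    epochs: int = 100,
    seed: int = 0,
    lr_start: float = 0.5,
    lr_end: float = 0.01,
) -> SOMModel:
    """Train a SOM with the classical online rule.

    Codebooks are initialised uniformly at random inside the per-feature
    data ranges.  The learning rate decays linearly from ``lr_start`` to
    ``lr_end`` and the Gaussian neighbourhood radius from
    ``max(rows, cols)/2`` to 1 over the epochs.  The per-epoch quantization
    error is recorded in ``training_log``.
    """
    X = features.values if hasattr(features, "values") else np.asarray(features, dtype=float)
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n, p = X.shape
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    codebook = rng.uniform(lo, hi, size=(rows * cols, p))
    pos = _grid_positions(rows, cols, topology)
    grid_d2 = cdist(pos, pos, "sqeuclidean")
    model = SOMModel(rows, cols, topology, codebook, [], pos)
    sigma0 = max(rows, cols) / 2.0
    sigma_end = 1.0
    for epoch in range(epochs):
        t = epoch / max(epochs - 1, 1)
        lr = lr_start + (lr_end - lr_start) * t
        sigma = sigma0 + (sigma_end - sigma0) * t
        order = rng.permutation(n)
        two_s2 = 2.0 * sigma * sigma
        for j in order:
            x = X[j]
            diff = x - codebook
            b = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-grid_d2[b] / two_s2)
            codebook += (lr * h)[:, None] * diff
        model.training_log.append(som_quantization_error(model, X))
    return model


def som_assign(model: SOMModel, features, unit_labels: np.ndarray) -> np.ndarray:
    """Map samples to cluster labels through their best-matching unit."""
    X = features.values if hasattr(features, "values") else np.asarray(features, dtype=float)
    return unit_labels[model.bmu(X)]
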