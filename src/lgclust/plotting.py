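"""Quick-look figures: postplots coloured by cluster label or local fDim."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["postplot", "loglog_plot"]


def postplot(pattern, values=None, path=None, title=None, point_size=2.0, cmap="viridis"):
    """Scatter a point pattern, optionally coloured by a per-point value."""
    fig, ax = plt.subplots(figsize=(7, 6))
    c = None if values is None else np.asarray(values)
    sc = ax.scatter(
        pattern.coords[:, 0], pattern.coords[:, 1], c=c, s=point_size, cmap=cmap, linewidths=0
    )
    if c is not None:
        fig.colorbar(sc, ax=ax)
    ax.set_aspect("equal")
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    if title:
        ax.set_title(title)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig


def loglog_plot(scales, values, fit=None, path=None, xlabel="scale", ylabel="count"):
    """Log-log curve with its fitted power law, as used for dimension fits."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.loglog(scales, values, "o-", ms=4)
    if fit is not None:
        s = np.asarray(scales, dtype=float)
        ax.loglog(s, np.exp(fit.intercept) * s**fit.slope, "--", label=f"slope {fit.slope:.3f}")
        ax.legend()
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
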