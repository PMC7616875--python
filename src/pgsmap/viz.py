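"""Convenience map rendering (not part of the analysis surface).

Node maps are drawn as coloured points on a diverging blue-to-red scale
(low to high), with a histogram of node values coloured the same way.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_node_map"]


def plot_node_map(coords, values, path, title: str = "", region=None) -> Path:
    """Point-map plus histogram for one node-valued surface."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    fig, (ax, hx) = plt.subplots(
        1, 2, figsize=(10, 4.5), gridspec_kw={"width_ratios": [2, 1]}
    )
    if region is not None:
        bx, by = region.exterior.xy
        ax.plot(bx, by, color="0.4", lw=0.8)
    sc = ax.scatter(
        coords[ok, 0], coords[ok, 1], c=values[ok], cmap="RdBu_r", s=12, marker="h"
    )
    fig.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_aspect("equal")
    ax.set_title(title)
    _, bins, patches = hx.hist(values[ok], bins=30)
    cmap = plt.get_cmap("RdBu_r")
    lo, hi = np.nanmin(values[ok]), np.nanmax(values[ok])
    for b0, b1, patch in zip(bins[:-1], bins[1:], patches):
        patch.set_facecolor(cmap(((b0 + b1) / 2 - lo) / ((hi - lo) or 1.0)))
    hx.set_xlabel("node value")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
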