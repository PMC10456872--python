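"""Simple visual checks: sub-space scatterplots and fitted polygons."""

from __future__ import annotations

import numpy as np

from .delta import LABELS, DeltaSeries, SubspacePartition, align_triplet
from .geometry import PolygonModel


def plot_polygon(model: PolygonModel, points=None, ax=None):
    """Draw a fitted containment polygon, its centroid fan and points."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if points is not None:
        pts = np.asarray(points).reshape(-1, 2)
        ax.plot(pts[:, 0], pts[:, 1], ".", ms=3, color="0.6", zorder=1)
    if not model.degenerate:
        closed = np.vstack([model.vertices, model.vertices[:1]])
        ax.plot(closed[:, 0], closed[:, 1], "-", color="tab:blue", lw=1.5)
        cx, cy = model.centroid
        for v in model.vertices:
            ax.plot([cx, v[0]], [cy, v[1]], "-", color="tab:blue", lw=0.5, alpha=0.5)
        ax.plot(cx, cy, "r+", ms=10)
    ax.set_xlabel("ΔBBI (nu)")
    ax.set_ylabel("ΔTT (nu)")
    return ax


def plot_subspaces(
    part: SubspacePartition,
    dbbi: DeltaSeries,
    dtt: DeltaSeries,
    containment: float = 0.95,
    axes=None,
):
    """One panel per sub-space (down / no-change / up) with its polygon."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(1, 3, figsize=(12, 4), sharex=True, sharey=True)
    point_sets = align_triplet(part, dbbi, dtt)
    titles = {"d": "down", "nc": "no change", "u": "up"}
    for ax, z in zip(axes, ("d", "nc", "u")):
        pts = point_sets[z]
        model = PolygonModel.fit(pts, containment) if pts.shape[0] else None
        if model is not None:
            plot_polygon(model, pts, ax=ax)
        ax.set_title(f"{part.driver} {titles[z]} (n={pts.shape[0]})")
    return axes
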