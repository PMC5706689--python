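"""Rendering of collision-probability maps.

One scaled, coloured circle per grid position across the device
cross-section, the conventional way of presenting the spatial probability
distribution of a transiting-animal collision model.
"""

from __future__ import annotations

import numpy as np

from .metrics import ProbabilityMap

__all__ = ["plot_probability_map"]


def plot_probability_map(
    pmap: ProbabilityMap,
    component: str = "total",
    ax=None,
    max_marker_area: float = 400.0,
):
    """Scatter the per-position probabilities as scaled coloured circles.

    ``component`` is one of ``total``, ``kite``, ``tether``.  Returns the
    matplotlib axes.
    """
    import matplotlib.pyplot as plt

    values = {
        "total": pmap.p_total,
        "kite": pmap.p_kite,
        "tether": pmap.p_tether,
    }[component]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 7))
    yy, zz = np.meshgrid(pmap.y, pmap.z)
    pct = 100.0 * values
    sc = ax.scatter(
        yy.ravel(),
        zz.ravel(),
        s=np.maximum(max_marker_area * values.ravel(), 4.0),
        c=pct.ravel(),
        cmap="viridis",
        vmin=0.0,
        vmax=100.0,
        edgecolors="k",
        linewidths=0.3,
    )
    ax.set_xlabel("y [m]")
    ax.set_ylabel("height above seabed [m]")
    ax.set_title(f"Collision probability (%) — {component}")
    ax.set_aspect("equal")
    ax.figure.colorbar(sc, ax=ax, label="probability [%]")
    return ax
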