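"""Diagnostic figures: the likelihood-mapping ternary plot and the
height/support scatter."""
from __future__ import annotations

import numpy as np

from .radiation import HeightSupportTable, RadiationResult

_SQRT3_2 = np.sqrt(3.0) / 2.0
# simplex corners for (p1, p2, p3): p1 top, p2 bottom-left, p3 bottom-right
_CORNERS = np.array([[0.5, _SQRT3_2], [0.0, 0.0], [1.0, 0.0]])


def barycentric_to_xy(weights) -> np.ndarray:
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    return w @ _CORNERS


def plot_ternary(results, ax=None, **scatter_kwargs):
    """Ternary scatter of quartet weights; accepts QuartetMappingResults
    or an iterable of (p1, p2, p3) triples."""
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4.6))
    weights = getattr(results, "weights", results)
    pts = barycentric_to_xy([getattr(w, "weights", w) for w in weights])
    tri = np.vstack([_CORNERS, _CORNERS[0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    ax.scatter(pts[:, 0], pts[:, 1], s=6, alpha=0.5, **scatter_kwargs)
    for label, (x, y), dy in (("T1", _CORNERS[0], 0.03), ("T2", _CORNERS[1], -0.06), ("T3", _CORNERS[2], -0.06)):
        ax.text(x, y + dy, label, ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    return ax


def plot_height_support(table, ax=None, **scatter_kwargs):
    """Relative node height vs nodal support, with the fitted line."""
    import matplotlib.pyplot as plt

    if isinstance(table, RadiationResult):
        table = table.height_support
    if isinstance(table, HeightSupportTable):
        df = table.frame
    else:
        df = table
    if ax is None:
        _fig, ax = plt.subplots(figsize=(5, 4))
    x, y = df["relative_height"].to_numpy(), df["support"].to_numpy()
    ax.scatter(x, y, s=14, **scatter_kwargs)
    if len(df) >= 2 and np.ptp(x) > 0:
        slope, intercept = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 10)
        ax.plot(xs, slope * xs + intercept, color="black", lw=1)
    ax.set_xlabel("relative node height")
    ax.set_ylabel("nodal support (%)")
    return ax
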