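"""Spatial visualization helpers: one dot per spot at its pixel position."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .io import SpotBarcode


def plot_spots(
    layout: Sequence[SpotBarcode],
    values: Mapping[str, float],
    ax=None,
    cmap: str = "viridis",
    size: float = 30.0,
    title: str | None = None,
):
    """Scatter spots at (pixel_x, pixel_y) colored by a per-barcode value.

    Spots missing from ``values`` or carrying NaN (e.g. zero-coverage
    barcodes in heteroplasmy maps) are drawn as hollow grey markers.
    Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    xs = np.array([s.pixel_x for s in layout])
    ys = np.array([s.pixel_y for s in layout])
    vals = np.array([values.get(s.barcode, np.nan) for s in layout], dtype=float)
    defined = np.isfinite(vals)
    if (~defined).any():
        ax.scatter(xs[~defined], ys[~defined], s=size, facecolors="none",
                   edgecolors="0.7", linewidths=0.5)
    sc = ax.scatter(xs[defined], ys[defined], c=vals[defined], s=size, cmap=cmap)
    ax.figure.colorbar(sc, ax=ax, shrink=0.8)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y grows downward
    ax.set_xlabel("pixel x")
    ax.set_ylabel("pixel y")
    if title:
        ax.set_title(title)
    return ax
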