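"""Minimal visualization helpers: colormapped PNG export of grids."""

from __future__ import annotations

import numpy as np

__all__ = ["save_field_png"]


def save_field_png(
    grid_values: np.ndarray,
    path,
    cmap: str = "viridis",
    value_range: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Write a field as an 8-bit colormapped PNG.

    The affine value -> gray mapping used is returned (and should be
    recorded next to the image when it is meant to be re-imported with
    :func:`elastopinn.phantoms.grayscale_to_field`).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(grid_values, dtype=float)
    lo, hi = value_range if value_range is not None else (arr.min(), arr.max())
    if hi <= lo:
        hi = lo + 1.0
    plt.imsave(path, arr, vmin=lo, vmax=hi, cmap=cmap, origin="lower")
    return float(lo), float(hi)
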