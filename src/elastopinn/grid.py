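"""Uniform collocated grids of material points.

All fields in this package live on a square ``q x q`` grid of material
points with physical spacing ``h`` (mm).  Arrays are indexed ``[i, j]``
with ``x = j * h`` and ``y = i * h``; i.e. axis 0 is the y direction and
axis 1 the x direction.  When an array is rendered as an image, y
therefore increases downward unless the renderer flips it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the material-point grid.

    Parameters
    ----------
    q : int
        Number of points per side (``q >= 3``).
    h : float
        Spacing between adjacent points, mm.
    t : float
        Plate thickness, mm.  Residual forces scale linearly in ``t``;
        the normalized residual loss is independent of it.
    """

    q: int
    h: float = 1.0
    t: float = 1.0

    def __post_init__(self) -> None:
        if self.q < 3:
            raise ValueError(f"grid needs q >= 3, got q={self.q}")
        if self.h <= 0 or self.t <= 0:
            raise ValueError("h and t must be positive")

    @property
    def extent(self) -> float:
        """Physical side length (q - 1) * h, mm."""
        return (self.q - 1) * self.h

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical coordinates ``(x, y)`` as two (q, q) arrays, mm."""
        c = np.arange(self.q) * self.h
        x, y = np.meshgrid(c, c, indexing="xy")
        return x, y

    def normalized_positions(self) -> np.ndarray:
        """Positions scaled to [-1, 1]^2 as an (q*q, 2) array.

        This is the input contract of the coordinate networks; mapping
        to the unit square keeps tanh/swish layers well conditioned
        regardless of the physical extent.
        """
        x, y = self.coordinates()
        half = self.extent / 2.0
        p = np.stack([(x.ravel() - half) / half, (y.ravel() - half) / half], axis=1)
        return p

    def node_index(self, i: int, j: int) -> int:
        """Flat index of grid point (row i, column j)."""
        return i * self.q + j
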