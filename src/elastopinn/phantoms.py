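"""Procedural elasticity phantoms and boundary loadings.

Everything downstream (FEM ground truth, network training, evaluation)
consumes synthetic inputs produced here: piecewise-smooth inclusion
fields with tissue-like moduli (E in [0.1, 1.0] MPa, nu in [0.1, 0.5])
and boundary displacements producing about 1% average normal strain —
the regime of quasi-static ultrasound elastography phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .fields import ElasticityField
from .grid import GridSpec

__all__ = [
    "RosePhantomSpec",
    "InclusionShape",
    "LoadingCase",
    "rose_modulus_field",
    "rose_petal_count",
    "inclusion_field",
    "boundary_displacements",
    "forward_boundary_data",
    "grayscale_to_field",
]


@dataclass(frozen=True)
class RosePhantomSpec:
    """A hard inclusion shaped like an overlapping-petal rose curve.

    The curve is r(theta) = sin(num/den * theta) in polar coordinates.
    With the default rational frequency 8/5 the petals overlap, and the
    local Young's modulus is set by how many petals cover a point:
    E = E_min + (count / max count) * (E_max - E_min).  An integer
    frequency would give disjoint petals and a binary field instead.
    """

    petal_numerator: int = 8
    petal_denominator: int = 5
    E_min: float = 0.1
    E_max: float = 1.0
    nu_const: float = 0.5
    center: tuple[float, float] | None = None  # physical (x, y), mm; None = grid center
    scale: float | None = None  # rose unit radius in mm; None = 0.45 * extent

    def __post_init__(self) -> None:
        if not (0 < self.E_min < self.E_max):
            raise ValueError("require 0 < E_min < E_max")
        if self.petal_numerator <= 0 or self.petal_denominator <= 0:
            raise ValueError("petal frequency must be positive")


def _rose_branches(num: int, den: int) -> int:
    # The curve r = sin((num/den) theta) closes over theta in
    # [0, 2*pi*den) when num*den is even, [0, pi*den) when odd.  Rays at
    # angle phi meet the curve at theta = phi + pi*n for n below.
    return 2 * den if (num * den) % 2 == 0 else den


def rose_petal_count(
    rho: np.ndarray, phi: np.ndarray, num: int = 8, den: int = 5
) -> np.ndarray:
    """Number of rose petals covering each point given in polar form.

    ``rho`` is the radius in rose units (petal tips at rho = 1) and
    ``phi`` the counterclockwise angle from the x axis.  A petal covers
    the point when the curve branch through the point's direction lies
    at or beyond the point's radius; branches with negative r are the
    petals traced on the opposite ray.
    """
    rho, phi = np.broadcast_arrays(
        np.asarray(rho, dtype=float), np.asarray(phi, dtype=float)
    )
    count = np.zeros(rho.shape, dtype=int)
    k = num / den
    for n in range(_rose_branches(num, den)):
        theta = phi + np.pi * n
        r = np.sin(k * theta)
        eff = r if n % 2 == 0 else -r
        count += (eff > 0) & (rho <= eff)
    return count


def rose_modulus_field(spec: RosePhantomSpec, grid: GridSpec) -> ElasticityField:
    """Build the rose phantom: modulus linear in the petal-overlap count.

    Background (zero petals) maps to ``E_min`` and the deepest overlap
    on the grid to ``E_max``; Poisson's ratio is uniform at
    ``spec.nu_const`` (0.5 = incompressible idealization).
    """
    x, y = grid.coordinates()
    cx, cy = spec.center if spec.center is not None else (grid.extent / 2,) * 2
    scale = spec.scale if spec.scale is not None else 0.45 * grid.extent
    if scale <= 0:
        raise ValueError("rose scale must be positive")
    rho = np.hypot(x - cx, y - cy) / scale
    phi = np.arctan2(y - cy, x - cx)
    count = rose_petal_count(rho, phi, spec.petal_numerator, spec.petal_denominator)
    cmax = count.max()
    if cmax == 0:
        raise ValueError("rose does not intersect the grid; enlarge scale")
    E = spec.E_min + count / cmax * (spec.E_max - spec.E_min)
    nu = np.full_like(E, spec.nu_const)
    return ElasticityField(E=E, nu=nu)


@dataclass(frozen=True)
class InclusionShape:
    """Elliptical (or circular) inclusion overwriting the background.

    ``E`` and/or ``nu`` may be None, leaving that component untouched —
    this is how phantoms with independent modulus and Poisson's-ratio
    patterns are composed.  ``smooth`` > 0 blends the edge over roughly
    that width in mm (tanh profile) instead of a hard step; smooth edges
    keep the discrete equilibrium stencils second-order consistent at
    the material boundary.
    """

    cx: float
    cy: float
    rx: float
    ry: float | None = None
    angle: float = 0.0  # radians, counterclockwise
    E: float | None = None
    nu: float | None = None
    smooth: float = 0.0  # edge blending width, mm (0 = sharp step)

    def _normalized_radius(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        ry = self.rx if self.ry is None else self.ry
        dx, dy = x - self.cx, y - self.cy
        c, s = np.cos(self.angle), np.sin(self.angle)
        u = c * dx + s * dy
        v = -s * dx + c * dy
        return np.sqrt((u / self.rx) ** 2 + (v / ry) ** 2)

    def mask(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self._normalized_radius(x, y) <= 1.0

    def weight(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Inclusion membership in [0, 1]: indicator for sharp edges, a
        tanh ramp of width ``smooth`` across the boundary otherwise."""
        rho = self._normalized_radius(x, y)
        if self.smooth <= 0.0:
            return (rho <= 1.0).astype(float)
        # signed distance to the boundary, approximated along the radius
        d = (rho - 1.0) * min(self.rx, self.rx if self.ry is None else self.ry)
        return 0.5 * (1.0 - np.tanh(d / self.smooth))


def inclusion_field(
    grid: GridSpec,
    background_E: float,
    background_nu: float,
    shapes: Sequence[InclusionShape] = (),
) -> ElasticityField:
    """Piecewise-smooth field; later shapes overwrite earlier ones."""
    x, y = grid.coordinates()
    E = np.full((grid.q, grid.q), float(background_E))
    nu = np.full((grid.q, grid.q), float(background_nu))
    for shape in shapes:
        w = shape.weight(x, y)
        if shape.E is not None:
            E = E + (shape.E - E) * w
        if shape.nu is not None:
            nu = nu + (shape.nu - nu) * w
    return ElasticityField(E=E, nu=nu)  # validates invariants


def grayscale_to_field(
    image: np.ndarray,
    grid: GridSpec,
    E_range: tuple[float, float] = (0.1, 1.0),
    nu_range: tuple[float, float] | float = 0.5,
) -> ElasticityField:
    """Map a grayscale array affinely onto (E, nu) grids.

    The image is resampled to the grid by nearest-neighbour lookup;
    pixel value 0 maps to the range minimum and the maximum pixel value
    to the range maximum.  A scalar ``nu_range`` gives a uniform
    Poisson's ratio.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale array")
    ii = np.clip((np.arange(grid.q) * img.shape[0] / grid.q).astype(int), 0, img.shape[0] - 1)
    jj = np.clip((np.arange(grid.q) * img.shape[1] / grid.q).astype(int), 0, img.shape[1] - 1)
    sub = img[np.ix_(ii, jj)]
    lo, hi = float(sub.min()), float(sub.max())
    unit = (sub - lo) / (hi - lo) if hi > lo else np.zeros_like(sub)
    E = E_range[0] + unit * (E_range[1] - E_range[0])
    if np.isscalar(nu_range):
        nu = np.full_like(E, float(nu_range))
    else:
        nu = nu_range[0] + unit * (nu_range[1] - nu_range[0])
    return ElasticityField(E=E, nu=nu)


LoadingMode = Literal["uniaxial-x", "uniaxial-y", "sinusoidal-top"]


@dataclass(frozen=True)
class LoadingCase:
    """Prescribed boundary displacements deforming the phantom.

    ``magnitude`` is the target average normal strain for the uniaxial
    modes (dimensionless, e.g. 0.01 for 1%) and the peak applied
    displacement in mm for ``sinusoidal-top`` (None = 1% of the extent,
    mimicking gentle transducer compression).
    """

    mode: LoadingMode
    magnitude: float | None = 0.01

    def __post_init__(self) -> None:
        if self.magnitude is not None and self.magnitude <= 0:
            raise ValueError("loading magnitude must be positive")
        if self.mode not in ("uniaxial-x", "uniaxial-y", "sinusoidal-top"):
            raise ValueError(f"unknown loading mode {self.mode!r}")


def boundary_displacements(
    case: LoadingCase, grid: GridSpec
) -> list[tuple[int, int, float]]:
    """Dirichlet data as (flat node index, component, value-in-mm) triples.

    Component 0 is u_x, 1 is u_y.  Uniaxial-x stretches between the
    left (u_x = 0) and right (u_x = s * extent) edges, with one corner
    pinned in y to remove the free translation; uniaxial-y is the same
    with x and y swapped.  Sinusoidal-top presses the top edge down with
    a half-sine peaking mid-edge while the bottom edge is held in y
    (laterally free, one node pinned in x).
    """
    q, L = grid.q, grid.extent
    bc: list[tuple[int, int, float]] = []
    if case.mode == "uniaxial-x":
        s = case.magnitude if case.magnitude is not None else 0.01
        for i in range(q):
            bc.append((grid.node_index(i, 0), 0, 0.0))
            bc.append((grid.node_index(i, q - 1), 0, s * L))
        bc.append((grid.node_index(0, 0), 1, 0.0))
    elif case.mode == "uniaxial-y":
        s = case.magnitude if case.magnitude is not None else 0.01
        for j in range(q):
            bc.append((grid.node_index(0, j), 1, 0.0))
            bc.append((grid.node_index(q - 1, j), 1, s * L))
        bc.append((grid.node_index(0, 0), 0, 0.0))
    else:  # sinusoidal-top
        amp = case.magnitude if case.magnitude is not None else 0.01 * L
        for j in range(q):
            xj = j * grid.h
            bc.append((grid.node_index(q - 1, j), 1, -amp * np.sin(np.pi * xj / L)))
            bc.append((grid.node_index(0, j), 1, 0.0))
        bc.append((grid.node_index(0, q // 2), 0, 0.0))
    return bc


def forward_boundary_data(case: LoadingCase, grid: GridSpec):
    """Complete boundary data for a forward problem: the Dirichlet
    displacements of the loading plus zero-traction conditions on the
    free edges (corners excluded — they belong to the gripped edges).

    A forward solve needs both: the equilibrium residual covers only
    interior subregions, so without the traction-free condition any
    traction distribution on the free edges would be admissible.
    """
    from .losses import BoundaryData

    q = grid.q
    bdata = BoundaryData.from_dirichlet(boundary_displacements(case, grid))
    idx, normals = [], []
    if case.mode in ("uniaxial-x", "uniaxial-y"):
        # uniaxial-x grips left/right, leaving top/bottom free (and
        # vice versa); exploit the x<->y symmetry of the grid layout
        for j in range(1, q - 1):
            if case.mode == "uniaxial-x":
                idx += [grid.node_index(0, j), grid.node_index(q - 1, j)]
            else:
                idx += [grid.node_index(j, 0), grid.node_index(j, q - 1)]
            n = [(0.0, -1.0), (0.0, 1.0)] if case.mode == "uniaxial-x" else [(-1.0, 0.0), (1.0, 0.0)]
            normals += n
    else:  # sinusoidal-top: lateral edges are free
        for i in range(1, q - 1):
            idx += [grid.node_index(i, 0), grid.node_index(i, q - 1)]
            normals += [(-1.0, 0.0), (1.0, 0.0)]
    bdata.trac_index = np.asarray(idx, dtype=int)
    bdata.trac_normal = np.asarray(normals, dtype=float)
    bdata.trac_value = np.zeros((len(idx), 2))
    return bdata
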