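"""Differentiable plane-stress mechanics on the material-point grid.

This is the physics sandwiched between the coordinate networks and the
loss: strain from displacement by finite differences, the isotropic
plane-stress constitutive relation, and the discrete equilibrium of
every 3x3 subregion expressed as a valid convolution with fixed signed
kernels.  Each operation ships with its adjoint (vector-Jacobian
product) so the training loop can backpropagate through the whole
pipeline without an autodiff framework; the adjoints are verified
against numerical differentiation in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import (
    DisplacementField,
    ElasticityField,
    ResidualForceMap,
    StrainField,
    StressField,
)
from .grid import GridSpec

__all__ = [
    "EquilibriumKernels",
    "DEFAULT_KERNELS",
    "diff_x",
    "diff_y",
    "diff_x_adjoint",
    "diff_y_adjoint",
    "compute_strain",
    "strain_adjoint",
    "constitutive_stress",
    "constitutive_vjp",
    "conv3_valid",
    "conv3_adjoint",
    "movsum3",
    "movsum3_adjoint",
    "residual_forces",
    "residual_forces_adjoint",
]


# ---------------------------------------------------------------------------
# finite differences (axis 1 = x, axis 0 = y)

def _diff_along(f: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Second-order derivative: central interior, one-sided edges."""
    f = np.asarray(f, dtype=float)
    if f.shape[axis] < 3:
        raise ValueError("need at least 3 points along the differentiated axis")
    f = np.moveaxis(f, axis, -1)
    d = np.empty_like(f)
    d[..., 1:-1] = (f[..., 2:] - f[..., :-2]) / (2 * h)
    d[..., 0] = (-3 * f[..., 0] + 4 * f[..., 1] - f[..., 2]) / (2 * h)
    d[..., -1] = (3 * f[..., -1] - 4 * f[..., -2] + f[..., -3]) / (2 * h)
    return np.moveaxis(d, -1, axis)


def _diff_along_adjoint(g: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Transpose of :func:`_diff_along` (as a linear map)."""
    g = np.moveaxis(np.asarray(g, dtype=float), axis, -1)
    a = np.zeros_like(g)
    # interior central differences
    a[..., 2:] += g[..., 1:-1]
    a[..., :-2] -= g[..., 1:-1]
    # one-sided stencils at the two edges
    a[..., 0] += -3 * g[..., 0]
    a[..., 1] += 4 * g[..., 0]
    a[..., 2] += -g[..., 0]
    a[..., -1] += 3 * g[..., -1]
    a[..., -2] += -4 * g[..., -1]
    a[..., -3] += g[..., -1]
    return np.moveaxis(a / (2 * h), -1, axis)


def diff_x(f: np.ndarray, h: float) -> np.ndarray:
    """d/dx on the grid (axis 1)."""
    return _diff_along(f, h, axis=1)


def diff_y(f: np.ndarray, h: float) -> np.ndarray:
    """d/dy on the grid (axis 0)."""
    return _diff_along(f, h, axis=0)


def diff_x_adjoint(g: np.ndarray, h: float) -> np.ndarray:
    return _diff_along_adjoint(g, h, axis=1)


def diff_y_adjoint(g: np.ndarray, h: float) -> np.ndarray:
    return _diff_along_adjoint(g, h, axis=0)


def compute_strain(disp: DisplacementField, grid: GridSpec) -> StrainField:
    """Small-strain kinematics: eps_xx, eps_yy, gamma_xy = du_x/dy + du_y/dx."""
    if disp.u_x.shape != (grid.q, grid.q):
        raise ValueError("displacement grid does not match GridSpec")
    return StrainField(
        eps_xx=diff_x(disp.u_x, grid.h),
        eps_yy=diff_y(disp.u_y, grid.h),
        gamma_xy=diff_y(disp.u_x, grid.h) + diff_x(disp.u_y, grid.h),
    )


def strain_adjoint(bar: StrainField, grid: GridSpec) -> DisplacementField:
    """Pull strain cotangents back to displacement cotangents."""
    du_x = diff_x_adjoint(bar.eps_xx, grid.h) + diff_y_adjoint(bar.gamma_xy, grid.h)
    du_y = diff_y_adjoint(bar.eps_yy, grid.h) + diff_x_adjoint(bar.gamma_xy, grid.h)
    return DisplacementField(u_x=du_x, u_y=du_y)


# ---------------------------------------------------------------------------
# constitutive relation (plane stress, isotropic)

def constitutive_stress(strain: StrainField, field: ElasticityField) -> StressField:
    """sigma = E/(1-nu^2) [[1,nu,0],[nu,1,0],[0,0,(1-nu)/2]] eps, pointwise."""
    E, nu = field.E, field.nu
    if np.any(nu >= 1):
        raise ValueError("Poisson's ratio must be below 1")
    c = E / (1.0 - nu**2)
    return StressField(
        sigma_xx=c * (strain.eps_xx + nu * strain.eps_yy),
        sigma_yy=c * (strain.eps_yy + nu * strain.eps_xx),
        tau_xy=c * (1.0 - nu) / 2.0 * strain.gamma_xy,
    )


def constitutive_vjp(
    strain: StrainField,
    field: ElasticityField,
    bar: StressField,
) -> tuple[StrainField, np.ndarray, np.ndarray]:
    """Cotangents of the constitutive map.

    Given dL/dsigma, returns (dL/deps, dL/dE, dL/dnu).  The relation is
    linear in eps and in E, so the strain pullback reuses the (symmetric)
    constitutive matrix and the E cotangent is sigma . bar / E.
    """
    E, nu = field.E, field.nu
    c = E / (1.0 - nu**2)
    s_xx = c * (strain.eps_xx + nu * strain.eps_yy)
    s_yy = c * (strain.eps_yy + nu * strain.eps_xx)
    t_xy = c * (1.0 - nu) / 2.0 * strain.gamma_xy

    d_eps = StrainField(
        eps_xx=c * (bar.sigma_xx + nu * bar.sigma_yy),
        eps_yy=c * (bar.sigma_yy + nu * bar.sigma_xx),
        gamma_xy=c * (1.0 - nu) / 2.0 * bar.tau_xy,
    )
    dE = (s_xx * bar.sigma_xx + s_yy * bar.sigma_yy + t_xy * bar.tau_xy) / E

    dc = E * 2.0 * nu / (1.0 - nu**2) ** 2
    d_nu = (
        (dc * (strain.eps_xx + nu * strain.eps_yy) + c * strain.eps_yy) * bar.sigma_xx
        + (dc * (strain.eps_yy + nu * strain.eps_xx) + c * strain.eps_xx) * bar.sigma_yy
        - E / (2.0 * (1.0 + nu) ** 2) * strain.gamma_xy * bar.tau_xy
    )
    return d_eps, dE, d_nu


# ---------------------------------------------------------------------------
# discrete equilibrium of 3x3 subregions

_DDX = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
_DDY = _DDX.T.copy()  # [[-1,-1,-1],[0,0,0],[1,1,1]]: rows indexed by increasing y
_ZERO = np.zeros((3, 3))


@dataclass(frozen=True)
class EquilibriumKernels:
    """The two sets of signed 3x3 stencils expressing net subregion force.

    x balance: sum F_x = conv(sigma_xx, w_xx) + conv(tau_xy, w_xy);
    y balance: sum F_y = conv(sigma_yy, w_yy) + conv(tau_xy, w_xy),
    with the y-balance kernels the transposes of the x-balance ones
    (component roles swapped).  Every kernel sums to zero, so uniform
    stress is exactly balanced.  Row index = increasing y (axis 0).
    """

    x_w_xx: np.ndarray = field(default_factory=lambda: _DDX.copy())
    x_w_yy: np.ndarray = field(default_factory=lambda: _ZERO.copy())
    x_w_xy: np.ndarray = field(default_factory=lambda: _DDY.copy())
    y_w_xx: np.ndarray = field(default_factory=lambda: _ZERO.copy())
    y_w_yy: np.ndarray = field(default_factory=lambda: _DDY.copy())
    y_w_xy: np.ndarray = field(default_factory=lambda: _DDX.copy())


DEFAULT_KERNELS = EquilibriumKernels()


def conv3_valid(f: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid correlation of a (q, q) grid with a 3x3 kernel -> (q-2, q-2).

    out[i, j] = sum_ab kernel[a, b] * f[i + a, j + b], matching the
    subregion sum with the window's top-left corner at (i, j).
    """
    q = f.shape[0]
    if q < 3:
        raise ValueError("grid too small for 3x3 subregions")
    p = q - 2
    out = np.zeros((p, p))
    for a in range(3):
        for b in range(3):
            k = kernel[a, b]
            if k != 0.0:
                out += k * f[a : a + p, b : b + p]
    return out


def conv3_adjoint(bar: np.ndarray, kernel: np.ndarray, q: int) -> np.ndarray:
    """Transpose of :func:`conv3_valid`: scatter (p, p) cotangents to (q, q)."""
    p = q - 2
    if bar.shape != (p, p):
        raise ValueError("cotangent shape does not match valid convolution output")
    out = np.zeros((q, q))
    for a in range(3):
        for b in range(3):
            k = kernel[a, b]
            if k != 0.0:
                out[a : a + p, b : b + p] += k * bar
    return out


_ONES = np.ones((3, 3))


def movsum3(f: np.ndarray) -> np.ndarray:
    """3x3 moving sum (sliding all-ones kernel), valid part."""
    return conv3_valid(f, _ONES)


def movsum3_adjoint(bar: np.ndarray, q: int) -> np.ndarray:
    return conv3_adjoint(bar, _ONES, q)


def residual_forces(
    stress: StressField,
    grid: GridSpec,
    kernels: EquilibriumKernels = DEFAULT_KERNELS,
) -> ResidualForceMap:
    """Net unbalanced force of every 3x3 subregion, scaled by h * t.

    Zero (to discretization order) exactly when the stress field
    satisfies the continuum equilibrium div(sigma) = 0.
    """
    ht = grid.h * grid.t
    e_x = ht * (
        conv3_valid(stress.sigma_xx, kernels.x_w_xx)
        + conv3_valid(stress.tau_xy, kernels.x_w_xy)
    )
    e_y = ht * (
        conv3_valid(stress.sigma_yy, kernels.y_w_yy)
        + conv3_valid(stress.tau_xy, kernels.y_w_xy)
    )
    return ResidualForceMap(e_x=e_x, e_y=e_y)


def residual_forces_adjoint(
    bar: ResidualForceMap,
    grid: GridSpec,
    kernels: EquilibriumKernels = DEFAULT_KERNELS,
) -> StressField:
    """Pull residual-map cotangents back to stress cotangents."""
    q = grid.q
    ht = grid.h * grid.t
    return StressField(
        sigma_xx=ht * conv3_adjoint(bar.e_x, kernels.x_w_xx, q),
        sigma_yy=ht * conv3_adjoint(bar.e_y, kernels.y_w_yy, q),
        tau_xy=ht
        * (
            conv3_adjoint(bar.e_x, kernels.x_w_xy, q)
            + conv3_adjoint(bar.e_y, kernels.y_w_xy, q)
        ),
    )
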