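"""Loss terms driving the training and their gradients.

Five terms appear across the three problem modes:

* ``loss_residual`` — normalized MAE of the subregion residual forces,
  each residual divided by the 3x3 moving sum of the predicted modulus
  (making the term invariant to a joint rescaling of stress and E);
* ``loss_boundary_displacement`` / ``loss_boundary_traction`` — MAE
  against prescribed displacements / tractions on boundary points
  (forward mode);
* ``loss_mean_elasticity`` — absolute deviation of the summed predicted
  modulus from a target sum, removing the multiplicative non-uniqueness
  of displacement-only inversion;
* ``loss_mean_displacement`` — absolute deviation of the predicted
  displacement mean from a target (default 0), pinning the constant
  left undetermined when only displacement derivatives enter the
  physics.

Totals: forward = w_r L_r + w_u L_u + w_f L_f; inverse = w_r L_r +
w_e L_e; mixed = w_r L_r + w_e L_e + w_d L_d.

Each ``*_with_grad`` variant returns the value together with the
cotangents with respect to its direct inputs, for the hand-rolled
reverse mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import DisplacementField, ResidualForceMap, StressField
from .mechanics import movsum3, movsum3_adjoint

__all__ = [
    "LossWeights",
    "BoundaryData",
    "ConstraintTargets",
    "loss_residual",
    "loss_residual_with_grad",
    "loss_boundary_displacement",
    "loss_boundary_displacement_with_grad",
    "loss_boundary_traction",
    "loss_boundary_traction_with_grad",
    "loss_mean_elasticity",
    "loss_mean_elasticity_with_grad",
    "loss_mean_displacement",
    "loss_mean_displacement_with_grad",
    "total_loss",
]


@dataclass
class LossWeights:
    """Nonnegative weights of the loss terms; terms absent from the
    active mode are ignored."""

    w_r: float = 1.0
    w_u: float = 1.0
    w_f: float = 1.0
    w_e: float = 1.0
    w_d: float = 1.0

    def __post_init__(self) -> None:
        if self.w_r <= 0:
            raise ValueError("w_r must be positive in every mode")
        for name in ("w_u", "w_f", "w_e", "w_d"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class BoundaryData:
    """Prescribed boundary displacements and/or tractions.

    Geometric part: ``disp_index`` flat node indices, ``disp_comp``
    components (0 = x, 1 = y), ``disp_value`` mm.  Force part:
    ``trac_index`` flat node indices, ``trac_normal`` (N, 2) outward
    unit normals, ``trac_value`` (N, 2) prescribed tractions in MPa.
    """

    disp_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    disp_comp: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    disp_value: np.ndarray = field(default_factory=lambda: np.empty(0))
    trac_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    trac_normal: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    trac_value: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @classmethod
    def from_dirichlet(cls, bc: list[tuple[int, int, float]]) -> "BoundaryData":
        """Build the geometric part from (node, component, value) triples."""
        if not bc:
            return cls()
        idx, comp, val = zip(*bc)
        return cls(
            disp_index=np.asarray(idx, dtype=int),
            disp_comp=np.asarray(comp, dtype=int),
            disp_value=np.asarray(val, dtype=float),
        )

    @property
    def n_u(self) -> int:
        return len(self.disp_index)

    @property
    def n_t(self) -> int:
        return len(self.trac_index)


@dataclass
class ConstraintTargets:
    """Targets of the mean-elasticity and mean-displacement constraints.

    ``mean_E_target`` (MPa) fixes the scale of the recovered modulus;
    with the true mean the recovery is absolute, with an arbitrary
    positive value it is relative.  ``mean_disp_target`` (mm) pins the
    undetermined constant of a predicted displacement component and
    does not affect the recovered elasticity.
    """

    mean_E_target: float = 1.0
    mean_disp_target: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_E_target <= 0:
            raise ValueError("mean_E_target must be positive")


# ---------------------------------------------------------------------------
# residual loss

def loss_residual_with_grad(
    res: ResidualForceMap, E_pred: np.ndarray
) -> tuple[float, ResidualForceMap, np.ndarray]:
    """Normalized residual MAE and its gradients.

    L_r = (1/p^2) sum_ij (|e_x| + |e_y|) / E_hat, where E_hat is the 3x3
    moving sum of the predicted modulus over the same subregions.
    Returns (value, dL/d e, dL/d E_pred).
    """
    E_pred = np.asarray(E_pred, dtype=float)
    Ehat = movsum3(E_pred)
    if np.any(Ehat <= 0):
        raise ValueError(
            "nonpositive 3x3 modulus sum: the elasticity head is unguarded"
        )
    if res.e_x.shape != Ehat.shape:
        raise ValueError("residual map does not match the modulus grid (p = q - 2)")
    p2 = res.e_x.size
    ax, ay = np.abs(res.e_x), np.abs(res.e_y)
    value = float(((ax + ay) / Ehat).sum() / p2)
    d_ex = np.sign(res.e_x) / (Ehat * p2)
    d_ey = np.sign(res.e_y) / (Ehat * p2)
    d_Ehat = -(ax + ay) / (Ehat**2 * p2)
    dE = movsum3_adjoint(d_Ehat, E_pred.shape[0])
    return value, ResidualForceMap(e_x=d_ex, e_y=d_ey), dE


def loss_residual(res: ResidualForceMap, E_pred: np.ndarray) -> float:
    return loss_residual_with_grad(res, E_pred)[0]


# ---------------------------------------------------------------------------
# boundary losses (forward mode)

def _gather(disp: DisplacementField, index: np.ndarray, comp: np.ndarray) -> np.ndarray:
    flat = np.stack([disp.u_x.ravel(), disp.u_y.ravel()], axis=1)
    return flat[index, comp]


def loss_boundary_displacement_with_grad(
    pred: DisplacementField, bdata: BoundaryData
) -> tuple[float, DisplacementField]:
    """MAE of predicted vs prescribed boundary displacements, with grad."""
    if bdata.n_u == 0:
        raise ValueError("no geometric boundary points: term is undefined")
    diff = _gather(pred, bdata.disp_index, bdata.disp_comp) - bdata.disp_value
    value = float(np.abs(diff).mean())
    gx = np.zeros_like(pred.u_x).ravel()
    gy = np.zeros_like(pred.u_y).ravel()
    s = np.sign(diff) / bdata.n_u
    mask_x = bdata.disp_comp == 0
    np.add.at(gx, bdata.disp_index[mask_x], s[mask_x])
    np.add.at(gy, bdata.disp_index[~mask_x], s[~mask_x])
    q = pred.u_x.shape[0]
    return value, DisplacementField(u_x=gx.reshape(q, q), u_y=gy.reshape(q, q))


def loss_boundary_displacement(pred: DisplacementField, bdata: BoundaryData) -> float:
    return loss_boundary_displacement_with_grad(pred, bdata)[0]


def loss_boundary_traction_with_grad(
    stress: StressField, bdata: BoundaryData
) -> tuple[float, StressField]:
    """MAE of predicted traction sigma . n vs prescribed, with grad."""
    if bdata.n_t == 0:
        raise ValueError("no traction boundary points: term is undefined")
    q = stress.sigma_xx.shape[0]
    sxx = stress.sigma_xx.ravel()[bdata.trac_index]
    syy = stress.sigma_yy.ravel()[bdata.trac_index]
    txy = stress.tau_xy.ravel()[bdata.trac_index]
    nx, ny = bdata.trac_normal[:, 0], bdata.trac_normal[:, 1]
    tx = sxx * nx + txy * ny
    ty = txy * nx + syy * ny
    dx = tx - bdata.trac_value[:, 0]
    dy = ty - bdata.trac_value[:, 1]
    n = 2 * bdata.n_t  # MAE over both traction components
    value = float((np.abs(dx).sum() + np.abs(dy).sum()) / n)
    sx_bar, sy_bar, t_bar = (np.zeros(q * q) for _ in range(3))
    np.add.at(sx_bar, bdata.trac_index, np.sign(dx) * nx / n)
    np.add.at(sy_bar, bdata.trac_index, np.sign(dy) * ny / n)
    np.add.at(t_bar, bdata.trac_index, (np.sign(dx) * ny + np.sign(dy) * nx) / n)
    return value, StressField(
        sigma_xx=sx_bar.reshape(q, q),
        sigma_yy=sy_bar.reshape(q, q),
        tau_xy=t_bar.reshape(q, q),
    )


def loss_boundary_traction(stress: StressField, bdata: BoundaryData) -> float:
    return loss_boundary_traction_with_grad(stress, bdata)[0]


# ---------------------------------------------------------------------------
# mean constraints

def loss_mean_elasticity_with_grad(
    E_pred: np.ndarray, targets: ConstraintTargets
) -> tuple[float, np.ndarray]:
    """L_e = |sum E_pred - sum E_target| / q^2 and its gradient."""
    E_pred = np.asarray(E_pred, dtype=float)
    n = E_pred.size
    dev = E_pred.sum() - targets.mean_E_target * n
    value = float(abs(dev)) / n
    grad = np.full_like(E_pred, np.sign(dev) / n)
    return value, grad


def loss_mean_elasticity(E_pred: np.ndarray, targets: ConstraintTargets) -> float:
    return loss_mean_elasticity_with_grad(E_pred, targets)[0]


def loss_mean_displacement_with_grad(
    u_pred: np.ndarray, targets: ConstraintTargets
) -> tuple[float, np.ndarray]:
    """L_d = |sum u_pred - r^2 * target| / r^2 and its gradient."""
    u_pred = np.asarray(u_pred, dtype=float)
    n = u_pred.size
    dev = u_pred.sum() - targets.mean_disp_target * n
    value = float(abs(dev)) / n
    grad = np.full_like(u_pred, np.sign(dev) / n)
    return value, grad


def loss_mean_displacement(u_pred: np.ndarray, targets: ConstraintTargets) -> float:
    return loss_mean_displacement_with_grad(u_pred, targets)[0]


# ---------------------------------------------------------------------------
# mode totals

_MODE_TERMS = {
    "forward": ("L_r", "L_u", "L_f"),
    "inverse": ("L_r", "L_e"),
    "mixed": ("L_r", "L_e", "L_d"),
}

_TERM_WEIGHT = {"L_r": "w_r", "L_u": "w_u", "L_f": "w_f", "L_e": "w_e", "L_d": "w_d"}


def total_loss(mode: str, components: dict[str, float], weights: LossWeights) -> float:
    """Weighted total for the given problem mode.

    ``components`` maps term names (L_r, L_u, L_f, L_e, L_d) to values;
    the terms required by the mode must be present, extras are ignored.
    Boundary terms with no data (L_u/L_f absent in forward mode) may be
    omitted by passing them as None — they are excluded from the sum.
    """
    if mode not in _MODE_TERMS:
        raise ValueError(f"unknown mode {mode!r}")
    total = 0.0
    for term in _MODE_TERMS[mode]:
        if term not in components:
            raise ValueError(f"{mode} mode requires loss component {term}")
        val = components[term]
        if val is None:
            if term == "L_r":
                raise ValueError("the residual loss cannot be omitted")
            continue
        total += getattr(weights, _TERM_WEIGHT[term]) * val
    return float(total)
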