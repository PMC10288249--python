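"""Core field containers shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Upper bound for Poisson's ratio.  0.5 itself is the incompressible
#: idealization; in plane stress the constitutive matrix stays finite
#: there, so it is allowed as a value.
NU_MAX = 0.5


@dataclass
class ElasticityField:
    """Gridded Young's modulus E (MPa) and Poisson's ratio nu."""

    E: np.ndarray
    nu: np.ndarray

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.E.shape != self.nu.shape:
            raise ValueError("E and nu grids must have the same shape")
        if np.any(self.E <= 0):
            raise ValueError("Young's modulus must be positive everywhere")
        if np.any(self.nu <= 0) or np.any(self.nu > NU_MAX):
            raise ValueError("Poisson's ratio must lie in (0, 0.5]")


@dataclass
class DisplacementField:
    """Gridded displacement components u_x, u_y (mm)."""

    u_x: np.ndarray
    u_y: np.ndarray

    def __post_init__(self) -> None:
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        if self.u_x.shape != self.u_y.shape:
            raise ValueError("u_x and u_y grids must have the same shape")


@dataclass
class StrainField:
    """Engineering strains: eps_xx, eps_yy and shear gamma_xy."""

    eps_xx: np.ndarray
    eps_yy: np.ndarray
    gamma_xy: np.ndarray


@dataclass
class StressField:
    """Plane-stress components sigma_xx, sigma_yy, tau_xy (MPa)."""

    sigma_xx: np.ndarray
    sigma_yy: np.ndarray
    tau_xy: np.ndarray


@dataclass
class ResidualForceMap:
    """Unbalanced x/y forces of every 3x3 subregion (MPa * mm^2).

    For a q x q stress grid the maps are p x p with p = q - 2 (valid
    convolution, no padding).  Both maps vanish identically for any
    spatially uniform stress state.
    """

    e_x: np.ndarray
    e_y: np.ndarray
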