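"""Plane-stress finite-element solver on bilinear quadrilaterals.

Ground-truth displacement fields for the synthetic phantoms are produced
by a standard displacement-based FEM: the q x q material-point grid is
meshed with (q-1)^2 four-node square elements, each integrated with 2x2
Gauss quadrature under the plane-stress constitutive matrix.  Element
properties are the average of the four corner values of the nodal
elasticity field (the networks predict nodal values, so the truth lives
on nodes).  Dirichlet data is imposed by elimination and the reduced
system solved by direct sparse factorization — exactness of the ground
truth matters more than speed at these sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fields import DisplacementField, ElasticityField
from .grid import GridSpec
from .mechanics import compute_strain

__all__ = ["FemSolution", "assemble_and_solve", "average_normal_strain"]

#: Poisson's ratio is clamped just below the incompressible limit inside
#: the constitutive matrix.  Plane stress remains finite at nu = 0.5, so
#: this is a no-op guard against user-supplied values straying above it.
_NU_CLAMP = 0.4999


@dataclass
class FemSolution:
    """Nodal displacements plus reactions on the constrained dofs."""

    displacement: DisplacementField
    reactions: np.ndarray  # (n_constrained,) forces, N (MPa * mm^2 / mm)
    constrained_dofs: np.ndarray  # global dof indices of the reactions
    grid: GridSpec


def _unit_square_stiffness_parts() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """8x8 integrals of B^T M_k B over a square Q4 element (2x2 Gauss).

    The plane-stress matrix decomposes as
    D = c * (M1 + nu * M2 + (1 - nu)/2 * M3) with c = E/(1 - nu^2),
    so the element stiffness is a per-element linear combination of
    three E/nu-independent 8x8 matrices.  For square elements of side h
    and thickness t the combination scales by t (h cancels).
    """
    m1 = np.diag([1.0, 1.0, 0.0])
    m2 = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    m3 = np.diag([0.0, 0.0, 1.0])
    g = 1.0 / np.sqrt(3.0)
    parts = [np.zeros((8, 8)) for _ in range(3)]
    # local corner order: (-1,-1), (1,-1), (1,1), (-1,1) — counterclockwise
    xi_c = np.array([-1.0, 1.0, 1.0, -1.0])
    eta_c = np.array([-1.0, -1.0, 1.0, 1.0])
    for xi in (-g, g):
        for eta in (-g, g):
            dN_dxi = 0.25 * xi_c * (1.0 + eta_c * eta)
            dN_deta = 0.25 * eta_c * (1.0 + xi_c * xi)
            # square element of side h: x = (xi+1) h/2, so d/dx = (2/h) d/dxi;
            # jacobian dA = (h/2)^2 dxi deta.  The h factors cancel in
            # B^T D B * dA; work with h = 2 (identity jacobian).
            B = np.zeros((3, 8))
            B[0, 0::2] = dN_dxi
            B[1, 1::2] = dN_deta
            B[2, 0::2] = dN_deta
            B[2, 1::2] = dN_dxi
            for part, m in zip(parts, (m1, m2, m3)):
                part += B.T @ m @ B
    return parts[0], parts[1], parts[2]


_K1, _K2, _K3 = _unit_square_stiffness_parts()


def _element_properties(field: ElasticityField) -> tuple[np.ndarray, np.ndarray]:
    """Per-element E, nu as the average of the 4 corner nodal values."""
    E, nu = field.E, field.nu
    E_el = 0.25 * (E[:-1, :-1] + E[:-1, 1:] + E[1:, :-1] + E[1:, 1:])
    nu_el = 0.25 * (nu[:-1, :-1] + nu[:-1, 1:] + nu[1:, :-1] + nu[1:, 1:])
    return E_el.ravel(), np.minimum(nu_el.ravel(), _NU_CLAMP)


def _assemble_stiffness(field: ElasticityField, grid: GridSpec) -> sp.csr_matrix:
    q = grid.q
    n_el = (q - 1) ** 2
    E_el, nu_el = _element_properties(field)
    c = grid.t * E_el / (1.0 - nu_el**2)

    # ke for all elements at once: (n_el, 8, 8)
    ke = (
        c[:, None, None] * _K1[None]
        + (c * nu_el)[:, None, None] * _K2[None]
        + (c * (1.0 - nu_el) / 2.0)[:, None, None] * _K3[None]
    )

    ii, jj = np.meshgrid(np.arange(q - 1), np.arange(q - 1), indexing="ij")
    n00 = (ii * q + jj).ravel()  # node (i, j)
    corner_nodes = np.stack([n00, n00 + 1, n00 + q + 1, n00 + q], axis=1)  # CCW
    dofs = np.empty((n_el, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * corner_nodes
    dofs[:, 1::2] = 2 * corner_nodes + 1

    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(2 * q * q, 2 * q * q))
    return K.tocsr()


def _check_rigid_modes(fixed_dofs: np.ndarray, grid: GridSpec) -> None:
    """Raise if the constraints leave a rigid-body mode unpinned.

    The null space of the unconstrained stiffness is spanned by the two
    translations and the in-plane rotation; the Dirichlet set removes
    them exactly when its restriction of those three modes has rank 3.
    """
    nodes = fixed_dofs // 2
    comps = fixed_dofs % 2
    x = (nodes % grid.q) * grid.h
    y = (nodes // grid.q) * grid.h
    m = np.zeros((len(fixed_dofs), 3))
    m[comps == 0, 0] = 1.0  # x translation
    m[comps == 1, 1] = 1.0  # y translation
    m[comps == 0, 2] = -y[comps == 0]  # rotation about z
    m[comps == 1, 2] = x[comps == 1]
    if np.linalg.matrix_rank(m, tol=1e-10 * max(1.0, grid.extent)) < 3:
        raise ValueError(
            "singular system: constraints leave rigid-body modes unpinned"
        )


def assemble_and_solve(
    field: ElasticityField,
    bc: list[tuple[int, int, float]],
    grid: GridSpec,
) -> FemSolution:
    """Solve K u = 0 under prescribed boundary displacements.

    ``bc`` lists (flat node index, component, value) as produced by
    :func:`elastopinn.phantoms.boundary_displacements`.  Raises if the
    constraints leave rigid-body modes (singular reduced system).
    """
    if field.E.shape != (grid.q, grid.q):
        raise ValueError("elasticity field does not match GridSpec")
    if not bc:
        raise ValueError("no boundary conditions: system is singular")
    K = _assemble_stiffness(field, grid)
    ndof = K.shape[0]
    u = np.zeros(ndof)
    fixed = np.array([2 * node + comp for node, comp, _ in bc], dtype=np.int64)
    vals = np.array([v for _, _, v in bc])
    order = np.argsort(fixed)
    fixed, vals = fixed[order], vals[order]
    if np.any(np.diff(fixed) == 0):
        dup = fixed[np.where(np.diff(fixed) == 0)]
        raise ValueError(f"duplicate constraints on dofs {np.unique(dup)}")
    u[fixed] = vals
    _check_rigid_modes(fixed, grid)
    free = np.setdiff1d(np.arange(ndof), fixed, assume_unique=True)

    rhs = -K[free][:, fixed] @ vals
    K_ff = K[free][:, free].tocsc()
    try:
        u_free = spla.spsolve(K_ff, rhs)
    except RuntimeError as exc:  # umfpack/superlu singularity
        raise ValueError("singular system: constraints leave rigid-body modes") from exc
    if not np.all(np.isfinite(u_free)):
        raise ValueError("singular system: constraints leave rigid-body modes")
    u[free] = u_free

    reactions = np.asarray(K[fixed] @ u).ravel()
    disp = DisplacementField(
        u_x=u[0::2].reshape(grid.q, grid.q),
        u_y=u[1::2].reshape(grid.q, grid.q),
    )
    return FemSolution(
        displacement=disp, reactions=reactions, constrained_dofs=fixed, grid=grid
    )


def average_normal_strain(sol: FemSolution, component: str, grid: GridSpec) -> float:
    """Mean eps_xx or eps_yy over the interior points of the solution."""
    strain = compute_strain(sol.displacement, grid)
    if component == "xx":
        arr = strain.eps_xx
    elif component == "yy":
        arr = strain.eps_yy
    else:
        raise ValueError("component must be 'xx' or 'yy'")
    return float(arr[1:-1, 1:-1].mean())
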