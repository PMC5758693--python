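"""Time-harmonic viscoelastic finite-element solver on the voxel grid.

Solves the steady-state (frequency-domain) linear viscoelastic problem

    (K(G*, K*) - omega^2 M) u = 0   on free DOFs,
    u prescribed on fixed/driven nodes,

where the element stiffness uses the complex shear and bulk moduli of the
Zener material at the excitation frequency and M is the consistent mass
matrix.  Damping enters exclusively through the imaginary parts of the
moduli; the dynamic operator is complex-symmetric (equal to its plain
transpose).

Element technology: 8-node trilinear hexahedra with selective reduced
integration — the deviatoric stiffness is integrated at 2x2x2 Gauss points,
the volumetric stiffness at the single centroid point.  This avoids
volumetric locking at the nearly incompressible Poisson ratios (nu = 0.499)
typical of soft tissue.

The linear system is solved by sparse complex LU factorization (SuperLU with
the symmetric-friendly MMD_AT_PLUS_A ordering) up to ~300k free DOFs, and by
ILU-preconditioned GMRES beyond that.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Tuple

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .phantom import BoundarySpec, MaterialMap, VoxelGrid, resolution_check
from .rheology import ZenerParams, complex_shear_modulus

__all__ = [
    "HarmonicField",
    "SingularSystemError",
    "ConvergenceError",
    "assemble_element_matrices",
    "assemble_operator",
    "solve_harmonic",
]

#: local node offsets of the trilinear hexahedron, unit-cube coordinates
_OFFSETS = np.array(
    [
        (0, 0, 0),
        (1, 0, 0),
        (0, 1, 0),
        (1, 1, 0),
        (0, 0, 1),
        (1, 0, 1),
        (0, 1, 1),
        (1, 1, 1),
    ],
    dtype=int,
)

_M_VOIGT = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])


class SingularSystemError(RuntimeError):
    """The harmonic system has unconstrained rigid-body modes."""


class ConvergenceError(RuntimeError):
    """Iterative solve failed; carries the residual history."""

    def __init__(self, message: str, residuals):
        super().__init__(message)
        self.residuals = list(residuals)


@dataclass(frozen=True)
class HarmonicField:
    """Complex steady-state displacement, m, one 3-vector per grid node."""

    grid: VoxelGrid
    values: np.ndarray  # complex, shape node_shape + (3,)
    frequency: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.complex128)
        expected = self.grid.node_shape + (3,)
        if values.shape != expected:
            raise ValueError(f"values shape {values.shape}, expected {expected}")
        if not np.all(np.isfinite(values.view(float))):
            raise ValueError("displacement field contains non-finite values")
        object.__setattr__(self, "values", values)


def _shape_gradients(xi: np.ndarray) -> np.ndarray:
    """d N_l / d xi_d at a unit-cube point; shape (8, 3)."""
    grads = np.empty((8, 3))
    for l, off in enumerate(_OFFSETS):
        vals = np.where(off == 1, xi, 1.0 - xi)
        signs = np.where(off == 1, 1.0, -1.0)
        for d in range(3):
            others = [vals[dd] for dd in range(3) if dd != d]
            grads[l, d] = signs[d] * others[0] * others[1]
    return grads


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (Voigt exx eyy ezz gxy gyz gzx), (6, 24)."""
    B = np.zeros((6, 24))
    for l in range(8):
        dx, dy, dz = grads[l]
        c = 3 * l
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


@lru_cache(maxsize=None)
def _unit_element_matrices() -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Geometry-only 24x24 blocks for a unit-spacing cube.

    Returns ``(A_dev, A_vol, M_unit)`` such that for spacing h and material
    moduli the element matrices are

        K_e = h * (G* A_dev + K* A_vol),     M_e = rho * h**3 * M_unit.
    """
    c_dev = np.diag([2.0, 2.0, 2.0, 1.0, 1.0, 1.0]) - (2.0 / 3.0) * np.outer(
        _M_VOIGT, _M_VOIGT
    )
    c_vol = np.outer(_M_VOIGT, _M_VOIGT)

    g = 0.5 / np.sqrt(3.0)
    pts_1d = np.array([0.5 - g, 0.5 + g])
    a_dev = np.zeros((24, 24))
    for px in pts_1d:
        for py in pts_1d:
            for pz in pts_1d:
                B = _b_matrix(_shape_gradients(np.array([px, py, pz])))
                a_dev += 0.125 * B.T @ c_dev @ B
    B0 = _b_matrix(_shape_gradients(np.array([0.5, 0.5, 0.5])))
    a_vol = B0.T @ c_vol @ B0

    m1 = np.array([[1.0 / 3.0, 1.0 / 6.0], [1.0 / 6.0, 1.0 / 3.0]])
    m_scalar = np.empty((8, 8))
    for l, ol in enumerate(_OFFSETS):
        for m, om in enumerate(_OFFSETS):
            m_scalar[l, m] = m1[ol[0], om[0]] * m1[ol[1], om[1]] * m1[ol[2], om[2]]
    m_unit = np.zeros((24, 24))
    for c in range(3):
        m_unit[c::3, c::3] = m_scalar
    return a_dev, a_vol, m_unit


def assemble_element_matrices(
    params: ZenerParams, frequency: float, spacing: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Complex 24x24 element stiffness and real consistent mass.

    Stiffness splits into a deviatoric part weighted by the complex shear
    modulus (2x2x2 Gauss) and a volumetric part weighted by the complex bulk
    modulus (single-point), both evaluated at the excitation frequency.
    """
    a_dev, a_vol, m_unit = _unit_element_matrices()
    cm = complex_shear_modulus(params, frequency)
    k_e = spacing * (cm.shear * a_dev + cm.bulk * a_vol)
    m_e = params.rho * spacing**3 * m_unit
    return k_e, m_e


def element_dofs(grid: VoxelGrid) -> np.ndarray:
    """DOF indices per element, shape (n_elements, 24), int32."""
    nsh = grid.node_shape
    ex, ey, ez = np.meshgrid(
        np.arange(grid.shape[0]),
        np.arange(grid.shape[1]),
        np.arange(grid.shape[2]),
        indexing="ij",
    )
    ex, ey, ez = ex.ravel(), ey.ravel(), ez.ravel()
    nodes = np.empty((ex.size, 8), dtype=np.int64)
    for l, (ox, oy, oz) in enumerate(_OFFSETS):
        nodes[:, l] = np.ravel_multi_index((ex + ox, ey + oy, ez + oz), nsh)
    dofs = (3 * nodes[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 24)
    return dofs.astype(np.int32)


def assemble_operator(mmap: MaterialMap, frequency: float) -> sp.csc_matrix:
    """Global dynamic operator A = K - omega^2 M, complex CSC."""
    grid = mmap.grid
    omega = 2.0 * np.pi * frequency
    dofs = element_dofs(grid)
    labels = mmap.labels.ravel()
    ndof = 3 * grid.n_nodes

    rows, cols, data = [], [], []
    for lab in mmap.present_labels:
        k_e, m_e = assemble_element_matrices(mmap.params_of(lab), frequency, grid.spacing)
        a_e = (k_e - omega**2 * m_e).astype(np.complex128)
        sel = dofs[labels == lab]
        n_sel = sel.shape[0]
        rows.append(np.repeat(sel, 24, axis=1).ravel())
        cols.append(np.tile(sel, (1, 24)).ravel())
        data.append(np.broadcast_to(a_e.ravel(), (n_sel, 576)).ravel())
    A = sp.coo_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    )
    return A.tocsc()


def _prescribed_dofs(bc: BoundarySpec) -> Tuple[np.ndarray, np.ndarray]:
    """Flat prescribed DOF indices and their complex values."""
    idx = [3 * bc.fixed_nodes[:, None] + np.arange(3)[None, :]]
    val = [np.zeros((bc.fixed_nodes.size, 3), dtype=np.complex128)]
    comp = np.nonzero(bc.drive_components)[0]
    if bc.driven_nodes.size and comp.size:
        idx.append(3 * bc.driven_nodes[:, None] + comp[None, :])
        val.append(
            np.broadcast_to(bc.drive_vector[comp], (bc.driven_nodes.size, comp.size))
        )
    return (
        np.concatenate([a.ravel() for a in idx]),
        np.concatenate([v.ravel() for v in val]),
    )


def _direct_solve(A_ff: sp.csc_matrix, rhs: np.ndarray, tol: float) -> np.ndarray:
    """Sparse LU solve via mixed-precision factorization.

    Factorizes in complex64 (roughly half the time and memory of complex128
    for these 3-D fill patterns) and recovers full double accuracy by
    iterative refinement on the complex128 residual; falls back to a full
    complex128 factorization in the rare case refinement stalls.
    """
    rhs_norm = np.linalg.norm(rhs)
    lu = spla.splu(A_ff.astype(np.complex64), permc_spec="MMD_AT_PLUS_A")
    x = lu.solve(rhs.astype(np.complex64)).astype(np.complex128)
    target = max(1e-12, 0.01 * tol)
    for _ in range(15):
        r = rhs - A_ff @ x
        if np.linalg.norm(r) <= target * rhs_norm:
            return x
        x = x + lu.solve(r.astype(np.complex64)).astype(np.complex128)
    lu = spla.splu(A_ff, permc_spec="MMD_AT_PLUS_A")
    return lu.solve(rhs)


def solve_harmonic(
    mmap: MaterialMap,
    bc: BoundarySpec,
    *,
    tol: float = 1e-8,
    min_resolution: float | None = 8.0,
    method: str = "auto",
    direct_dof_limit: int = 300_000,
    maxiter: int = 2000,
) -> HarmonicField:
    """Steady-state complex displacement field for one excitation.

    Parameters
    ----------
    tol : float
        Relative residual bound on the free equations.
    min_resolution : float or None
        Floor on elements per shear wavelength (None disables the check).
    method : {"auto", "direct", "iterative"}
        "auto" picks direct factorization up to ``direct_dof_limit`` free
        DOFs, preconditioned GMRES beyond.
    """
    if min_resolution is not None:
        ratio = resolution_check(mmap, bc.frequency)
        if ratio < min_resolution:
            raise ValueError(
                f"grid resolves only {ratio:.1f} elements per shear wavelength "
                f"(< floor {min_resolution}); refine the grid or lower the floor"
            )
    grid = mmap.grid
    ndof = 3 * grid.n_nodes
    pres_idx, pres_val = _prescribed_dofs(bc)
    if pres_idx.size == 0:
        raise SingularSystemError(
            "no prescribed DOFs: the harmonic system retains rigid-body modes"
        )

    u = np.zeros(ndof, dtype=np.complex128)
    u[pres_idx] = pres_val
    if np.linalg.norm(pres_val) == 0.0:
        # homogeneous Dirichlet data drives nothing: the zero field solves it
        return HarmonicField(
            grid=grid,
            values=u.reshape(grid.node_shape + (3,)),
            frequency=bc.frequency,
        )

    A = assemble_operator(mmap, bc.frequency)
    free = np.setdiff1d(np.arange(ndof, dtype=np.int64), pres_idx)
    A_csr = A.tocsr()
    rhs = -(A_csr[free][:, pres_idx] @ pres_val)
    A_ff = A_csr[free][:, free].tocsc()

    if method == "auto":
        method = "direct" if free.size <= direct_dof_limit else "iterative"
    if method == "direct":
        u_f = _direct_solve(A_ff, rhs, tol)
    elif method == "iterative":
        ilu = spla.spilu(A_ff, drop_tol=1e-5, fill_factor=20)
        M = spla.LinearOperator(A_ff.shape, ilu.solve)
        residuals: list[float] = []
        u_f, info = spla.gmres(
            A_ff,
            rhs,
            rtol=tol,
            maxiter=maxiter,
            M=M,
            callback=residuals.append,
            callback_type="pr_norm",
        )
        if info != 0:
            raise ConvergenceError(
                f"GMRES failed to reach rtol={tol} in {maxiter} iterations",
                residuals,
            )
    else:
        raise ValueError(f"unknown method {method!r}")

    res = np.linalg.norm(A_ff @ u_f - rhs) / np.linalg.norm(rhs)
    if res > max(tol, 1e-10):
        raise ConvergenceError(
            f"free-equation residual {res:.2e} exceeds tolerance {tol:.2e}", [res]
        )
    u[free] = u_f
    return HarmonicField(
        grid=grid, values=u.reshape(grid.node_shape + (3,)), frequency=bc.frequency
    )
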