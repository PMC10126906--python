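"""Mechanical-signal fields on the voxel grid.

Three scalar descriptors of the local mechanical environment are supported,
all derived from a strain-energy-density (SED, MPa) field produced by
linear-elastic voxel finite-element analysis:

* **SED** itself, sampled on the bone side of the bone/marrow interface;
* **effective strain** ``sqrt(2 U / E)`` in microstrain, also bone-side —
  a modulus-aware scalar strain measure;
* **the norm of the SED gradient** (central differences), a proxy for
  interstitial fluid flow, sampled on the marrow side of the interface.

The module also provides material-map handling (homogeneous bone/marrow
moduli or a density-derived heterogeneous modulus field with a lower
clamp), linear rescaling of the fields to a target applied force, and a
small-grid matrix-free voxel FE solver (8-node hexahedra, 2x2x2 Gauss
quadrature, Jacobi-preconditioned conjugate gradients) for producing SED
fields on desk-scale problems.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gridio import BinaryVolume, ScalarVolume
from .remodel import FACE_OFFSETS, _shifted

__all__ = [
    "MaterialMap",
    "SignalField",
    "SAMPLING_SIDE",
    "effective_strain_field",
    "sed_gradient_norm",
    "density_to_modulus",
    "rescale_to_force",
    "sample_surface_signal",
    "microfe_solve",
]

#: which side of the bone/marrow interface each signal kind is sampled on
SAMPLING_SIDE = {"sed": "bone", "effective_strain": "bone", "grad_sed_norm": "marrow"}


@dataclass
class MaterialMap:
    """Material assignment for voxel FE.

    Homogeneous mode assigns ``E_bone`` (default 14800 MPa) to bone voxels
    and ``E_marrow`` (default 2 MPa) to marrow; heterogeneous mode maps
    density linearly to modulus (``slope * density + intercept``) with a
    lower clamp at ``E_min`` (default 2 MPa).  Poisson's ratio 0.3 is
    shared by both modes.
    """

    mode: str = "homogeneous"
    E_bone: float = 14800.0
    E_marrow: float = 2.0
    poisson: float = 0.3
    density_slope: float | None = None
    density_intercept: float | None = None
    E_min: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown material mode: {self.mode}")
        if not (0 <= self.poisson < 0.5):
            raise ValueError("Poisson's ratio must be in [0, 0.5)")
        if self.E_bone <= 0 or self.E_marrow <= 0 or self.E_min <= 0:
            raise ValueError("moduli must be positive")

    def modulus_field(self, bone: BinaryVolume) -> ScalarVolume:
        """Homogeneous per-voxel modulus field (MPa) from a binary image."""
        E = np.where(bone.bool_data, self.E_bone, self.E_marrow)
        return ScalarVolume(E.astype(np.float64), bone.voxel_size)


@dataclass
class SignalField:
    """A mechanical-signal volume with its sampling-side convention."""

    kind: str
    data: ScalarVolume

    def __post_init__(self) -> None:
        if self.kind not in SAMPLING_SIDE:
            raise ValueError(f"unknown signal kind: {self.kind}")
        if np.any(self.data.data < 0):
            raise ValueError("signal fields must be non-negative")

    @property
    def sampling_side(self) -> str:
        return SAMPLING_SIDE[self.kind]


def effective_strain_field(sed: ScalarVolume, E_field: ScalarVolume) -> SignalField:
    """Effective strain ``sqrt(2 U / E)`` in microstrain, voxel-wise."""
    if np.any(sed.data < 0):
        raise ValueError("SED must be non-negative")
    if np.any(E_field.data <= 0):
        raise ValueError("modulus field must be positive")
    eps = np.sqrt(2.0 * sed.data / E_field.data) * 1e6
    return SignalField("effective_strain", ScalarVolume(eps, sed.voxel_size))


def sed_gradient_norm(sed: ScalarVolume) -> SignalField:
    """Euclidean norm of the SED gradient (MPa/µm).

    Central differences in the interior, one-sided at the boundary, with
    the voxel size as grid spacing.
    """
    if min(sed.shape) < 3:
        raise ValueError("gradient needs >= 3 voxels along every axis")
    gz, gy, gx = np.gradient(sed.data.astype(np.float64), sed.voxel_size)
    norm = np.sqrt(gz**2 + gy**2 + gx**2)
    return SignalField("grad_sed_norm", ScalarVolume(norm, sed.voxel_size))


def density_to_modulus(density: ScalarVolume, mat: MaterialMap) -> ScalarVolume:
    """Heterogeneous modulus field: ``max(slope*density + intercept, E_min)``."""
    if mat.mode != "heterogeneous":
        raise ValueError("density_to_modulus requires heterogeneous mode")
    if mat.density_slope is None or mat.density_intercept is None:
        raise ValueError("heterogeneous mode needs density_slope and density_intercept")
    E = mat.density_slope * density.data + mat.density_intercept
    return ScalarVolume(np.maximum(E, mat.E_min), density.voxel_size)


def rescale_to_force(field: SignalField, F_fe: float, F_target: float) -> SignalField:
    """Linear-elastic rescaling of a signal field to a target applied force.

    Displacement-linear quantities (effective strain) scale with
    ``k = F_target / F_fe``; energy-derived quantities (SED and its
    gradient norm) scale with ``k**2``.
    """
    if F_fe <= 0 or F_target <= 0:
        raise ValueError("forces must be positive")
    k = F_target / F_fe
    factor = k if field.kind == "effective_strain" else k * k
    return SignalField(
        field.kind, ScalarVolume(field.data.data * factor, field.data.voxel_size)
    )


def sample_surface_signal(
    field: SignalField, table: pd.DataFrame, bone: BinaryVolume
) -> pd.DataFrame:
    """Fill the surface table's ``signal`` column from a signal field.

    Bone-side kinds (SED, effective strain) read the field at the surface
    voxel itself; the marrow-side kind (gradient norm) averages the field
    over the voxel's in-bounds marrow 6-neighbors.
    """
    if field.data.shape != bone.shape:
        raise ValueError("field/bone shape mismatch")
    z = table["z"].to_numpy()
    y = table["y"].to_numpy()
    x = table["x"].to_numpy()
    if field.sampling_side == "bone":
        sig = field.data.data[z, y, x]
    else:
        marrow = ~bone.bool_data
        num = np.zeros(bone.shape)
        cnt = np.zeros(bone.shape)
        vals = np.where(marrow, field.data.data, 0.0)
        for off in FACE_OFFSETS:
            num += _shifted(vals, off, fill=0.0)
            cnt += _shifted(marrow.astype(np.float64), off, fill=0.0)
        c = cnt[z, y, x]
        if np.any(c == 0):
            raise ValueError("surface voxel with no in-bounds marrow neighbor")
        sig = num[z, y, x] / c
    out = table.copy()
    out["signal"] = sig.astype(np.float64)
    return out


# ---------------------------------------------------------------------------
# Small-grid voxel finite elements
# ---------------------------------------------------------------------------

_GAUSS = (-1.0 / np.sqrt(3.0), 1.0 / np.sqrt(3.0))

# local node order: l = dz*4 + dy*2 + dx
_LOCAL_NODES = [(dz, dy, dx) for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)]


def _isotropic_C(nu: float) -> np.ndarray:
    """Voigt elasticity matrix for E = 1 (engineering shear strains)."""
    lam = nu / ((1 + nu) * (1 - 2 * nu))
    mu = 1.0 / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


def _hex_stiffness(nu: float) -> np.ndarray:
    """24x24 stiffness of the unit-cube trilinear hexahedron, E = 1.

    Dof order: node-major in ``_LOCAL_NODES`` order, components (x, y, z)
    within each node.  For an isotropic cube of edge ``h`` and modulus
    ``E`` the element stiffness is ``E * h * K``.
    """
    C = _isotropic_C(nu)
    signs = np.array([[2 * dx - 1, 2 * dy - 1, 2 * dz - 1] for dz, dy, dx in _LOCAL_NODES])
    K = np.zeros((24, 24))
    for zt in _GAUSS:
        for yt in _GAUSS:
            for xt in _GAUSS:
                xi = np.array([xt, yt, zt])
                dN = np.empty((8, 3))
                for l in range(8):
                    s = signs[l]
                    for j in range(3):
                        term = s[j] / 8.0
                        for k in range(3):
                            if k != j:
                                term *= 1 + s[k] * xi[k]
                        dN[l, j] = term
                dN = dN * 2.0  # unit cube: d(xi)/dx = 2
                B = np.zeros((6, 24))
                for l in range(8):
                    bx, by, bz = dN[l]
                    c = 3 * l
                    B[0, c] = bx
                    B[1, c + 1] = by
                    B[2, c + 2] = bz
                    B[3, c] = by
                    B[3, c + 1] = bx
                    B[4, c + 1] = bz
                    B[4, c + 2] = by
                    B[5, c] = bz
                    B[5, c + 2] = bx
                K += B.T @ C @ B * 0.125  # detJ of the unit cube
    return K


def microfe_solve(
    E_field: ScalarVolume,
    poisson: float = 0.3,
    axial_strain: float = 0.01,
    bc_mode: str = "paper",
    tol: float = 1e-8,
    maxiter: int = 20000,
    size_cap: int = 64,
) -> tuple[ScalarVolume, float]:
    """Linear elasticity on a uniform voxel mesh; returns (SED, reaction).

    Each voxel becomes an 8-node hexahedral element with modulus
    ``E_field`` (MPa) and a shared Poisson's ratio.  Boundary conditions:

    * ``bc_mode="paper"`` — the proximal (z = 0) node layer is fixed in
      all directions and the distal (z = L) layer is displaced axially by
      ``axial_strain * L`` (lateral components free); lateral faces are
      traction-free.
    * ``bc_mode="affine"`` — every boundary node is prescribed the affine
      field of uniform uniaxial strain with lateral contraction
      ``-poisson * axial_strain``; for a homogeneous block this problem's
      exact solution is the affine field itself.

    The system is solved matrix-free with Jacobi-preconditioned conjugate
    gradients to relative residual ``tol``; the returned SED is the
    element-averaged strain energy density in MPa and the reaction is the
    total axial force (N) on the displaced face.
    """
    if bc_mode not in ("paper", "affine"):
        raise ValueError(f"unknown bc_mode: {bc_mode}")
    if np.any(E_field.data <= 0):
        raise ValueError("modulus field must be positive")
    nz, ny, nx = E_field.shape
    if max(nz, ny, nx) > size_cap:
        raise ValueError(f"grid {E_field.shape} exceeds size cap {size_cap}")
    h = E_field.voxel_size * 1e-3  # mm, so MPa * mm^2 = N
    nu = float(poisson)
    K1 = _hex_stiffness(nu)

    nnz, nny, nnx = nz + 1, ny + 1, nx + 1
    nnode = nnz * nny * nnx
    ndof = nnode * 3

    # element -> 24 global dof indices
    ez, ey, ex = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    ez, ey, ex = ez.ravel(), ey.ravel(), ex.ravel()
    dof_idx = np.empty((ez.size, 24), dtype=np.int64)
    for l, (dz, dy, dx) in enumerate(_LOCAL_NODES):
        node = ((ez + dz) * nny + (ey + dy)) * nnx + (ex + dx)
        for c in range(3):
            dof_idx[:, 3 * l + c] = 3 * node + c
    scale = (E_field.data.ravel() * h).astype(np.float64)

    def matvec(u: np.ndarray) -> np.ndarray:
        ue = u[dof_idx]
        fe = (ue @ K1) * scale[:, None]
        return np.bincount(dof_idx.ravel(), weights=fe.ravel(), minlength=ndof)

    # node coordinates (physical, mm)
    gz, gy, gx = np.meshgrid(
        np.arange(nnz), np.arange(nny), np.arange(nnx), indexing="ij"
    )
    Z = (gz.ravel() * h).astype(np.float64)
    Y = (gy.ravel() * h).astype(np.float64)
    X = (gx.ravel() * h).astype(np.float64)
    eps = float(axial_strain)
    affine = np.empty((nnode, 3))
    affine[:, 0] = -nu * eps * X
    affine[:, 1] = -nu * eps * Y
    affine[:, 2] = eps * Z

    fixed = np.zeros((nnode, 3), dtype=bool)
    u = np.zeros((nnode, 3))
    boundary = (
        (gz.ravel() == 0)
        | (gz.ravel() == nz)
        | (gy.ravel() == 0)
        | (gy.ravel() == ny)
        | (gx.ravel() == 0)
        | (gx.ravel() == nx)
    )
    top = gz.ravel() == nz
    if bc_mode == "affine":
        fixed[boundary, :] = True
        u[:] = affine  # prescribed on the boundary, initial guess inside
    else:
        bottom = gz.ravel() == 0
        fixed[bottom, :] = True
        fixed[top, 2] = True
        u[:, 2] = eps * Z  # linear interpolation as initial guess
        u[bottom] = 0.0
    u = u.ravel()
    free = ~fixed.ravel()

    # right-hand side: -K u_bc restricted to free dofs
    u_bc = u.copy()
    u_bc[free] = 0.0
    b = -matvec(u_bc)
    b[~free] = 0.0
    bnorm = np.linalg.norm(b)

    diag_e = np.repeat(np.diag(K1)[None, :], ez.size, axis=0) * scale[:, None]
    diag = np.bincount(dof_idx.ravel(), weights=diag_e.ravel(), minlength=ndof)
    inv_diag = np.where(free, 1.0 / np.maximum(diag, 1e-300), 0.0)

    # u already carries the prescribed values, so the free-dof residual of
    # K_ff u_f = -K_fb u_b is simply -(K u) restricted to the free dofs
    r = -matvec(u)
    r[~free] = 0.0
    if bnorm == 0.0:
        bnorm = max(np.linalg.norm(r), 1.0)
    if np.linalg.norm(r) > tol * bnorm:
        z = inv_diag * r
        p = z.copy()
        rz = float(r @ z)
        converged = False
        for _ in range(maxiter):
            Ap = matvec(p)
            Ap[~free] = 0.0
            alpha = rz / float(p @ Ap)
            u += alpha * p
            r -= alpha * Ap
            if np.linalg.norm(r) <= tol * bnorm:
                converged = True
                break
            z = inv_diag * r
            rz_new = float(r @ z)
            p = z + (rz_new / rz) * p
            rz = rz_new
        if not converged:
            raise RuntimeError(
                f"conjugate gradients did not reach tol {tol} in {maxiter} iterations"
            )

    ue = u[dof_idx]
    energy = 0.5 * np.einsum("ij,ij->i", ue, ue @ K1) * scale
    sed = (energy / h**3).reshape(nz, ny, nx)
    sed = np.maximum(sed, 0.0)  # energy is non-negative; clip roundoff

    f = matvec(u)
    top_z_dofs = 3 * np.flatnonzero(top) + 2
    reaction = float(f[top_z_dofs].sum())
    return ScalarVolume(sed, E_field.voxel_size), reaction
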