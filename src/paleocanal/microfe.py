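"""Voxel micro-finite-element homogenization of three-phase cortical bone.

Each voxel of a label volume becomes one 8-node trilinear hexahedral
element with small-strain isotropic elasticity; canal voxels carry the
material of the chosen scenario (``solid`` = bone, i.e. a pore-free
control; ``liquid`` = a soft near-incompressible solid standing in for
blood/tissue; ``gas`` = a vanishingly stiff filler, since a true zero
modulus is singular).  Uniaxial and shear load cases under prescribed
face displacements yield the effective orthotropic engineering constants,
labeled in cylindrical axes (r = x, theta = y, z longitudinal) as for a
thin element of a cylindrical bone wall.

The linear systems are solved matrix-free (element-by-element, one
reference stiffness per material) with a conjugate-gradient iteration,
node-block-Jacobi preconditioning and a coarse-grid (factor-2) initial
guess, which keeps memory linear in elements and handles the million-dof
meshes that voxel models produce.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numba
import numpy as np

from .io import BACKGROUND, BONE, CANAL, LabelVolume

__all__ = [
    "Material",
    "MaterialSpec",
    "LoadCase",
    "StressField",
    "EngineeringConstants",
    "VoxelMesh",
    "hex_stiffness",
    "assign_materials",
    "solve_case",
    "element_stresses",
    "homogenize",
    "mean_density",
    "voigt_modulus",
    "reuss_modulus",
    "SCENARIOS",
]

SCENARIOS = ("solid", "liquid", "gas")


@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic phase: E in GPa, Poisson nu, density g/cm^3."""

    E: float
    nu: float
    rho: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("E must be > 0 (use a small positive value for gas)")
        if not -1.0 < self.nu < 0.5:
            raise ValueError("nu must lie strictly in (-1, 0.5)")
        if self.rho < 0:
            raise ValueError("rho must be >= 0")

    @property
    def lame(self) -> tuple[float, float]:
        lam = self.E * self.nu / ((1 + self.nu) * (1 - 2 * self.nu))
        mu = self.E / (2 * (1 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class MaterialSpec:
    """Per-phase materials for the three canal scenarios.

    Canal-phase values are order-of-magnitude engineering choices relative
    to bone: the liquid is water-like (bulk modulus ~2.2 GPa via a
    near-incompressible soft solid), the gas is "effectively zero"
    stiffness (1e-6 of bone; exactly zero is singular).  The liquid
    density is set so that at 16 % porosity the liquid scenario carries
    5 % less mean density than solid bone.
    """

    bone: Material = Material(E=20.0, nu=0.3, rho=2.0)
    canal_liquid: Material = Material(E=0.132, nu=0.49, rho=1.375)
    canal_gas: Material = Material(E=2.0e-5, nu=0.0, rho=0.0012)

    def canal_material(self, scenario: str) -> Material:
        if scenario == "solid":
            return self.bone
        if scenario == "liquid":
            return self.canal_liquid
        if scenario == "gas":
            return self.canal_gas
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


@dataclass(frozen=True)
class LoadCase:
    """A prescribed-strain case: uniaxial along an axis or shear in a plane.

    ``axis``: "x" | "y" | "z" for uniaxial; ``plane``: "xy" | "yz" | "zx"
    for shear (first letter = displaced component, second = gradient
    direction).
    """

    kind: str  # "uniaxial" | "shear"
    axis: str = "z"
    applied_strain: float = 0.02

    def __post_init__(self) -> None:
        if self.kind not in ("uniaxial", "shear"):
            raise ValueError("kind must be 'uniaxial' or 'shear'")
        if self.applied_strain < 0:
            raise ValueError("applied_strain must be >= 0")
        ok = ("x", "y", "z") if self.kind == "uniaxial" else ("xy", "yz", "zx")
        if self.axis not in ok:
            raise ValueError(f"axis {self.axis!r} invalid for {self.kind}; expected {ok}")


# ---------------------------------------------------------------------------
# element stiffness


def _elastic_C(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[np.arange(3), np.arange(3)] += 2 * mu
    C[3:, 3:] = np.eye(3) * mu
    return C


# local node order: (0,0,0),(1,0,0),(1,1,0),(0,1,0),(0,0,1),(1,0,1),(1,1,1),(0,1,1)
_LOCAL = np.array(
    [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1)],
    dtype=float,
)
_XI = _LOCAL * 2.0 - 1.0  # natural coordinates of the nodes


def _shape_grad(xi: np.ndarray) -> np.ndarray:
    """(8, 3) gradients of the trilinear shape functions at natural xi."""
    g = np.empty((8, 3))
    for a in range(8):
        sx, sy, sz = _XI[a]
        g[a, 0] = 0.125 * sx * (1 + sy * xi[1]) * (1 + sz * xi[2])
        g[a, 1] = 0.125 * sy * (1 + sx * xi[0]) * (1 + sz * xi[2])
        g[a, 2] = 0.125 * sz * (1 + sx * xi[0]) * (1 + sy * xi[1])
    return g


def _b_matrix(grad_xyz: np.ndarray) -> np.ndarray:
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grad_xyz[a]
        B[0, 3 * a] = gx
        B[1, 3 * a + 1] = gy
        B[2, 3 * a + 2] = gz
        B[3, 3 * a] = gy
        B[3, 3 * a + 1] = gx
        B[4, 3 * a + 1] = gz
        B[4, 3 * a + 2] = gy
        B[5, 3 * a] = gz
        B[5, 3 * a + 2] = gx
    return B


def hex_stiffness(material: Material, h: tuple[float, float, float]) -> np.ndarray:
    """24x24 stiffness of a rectangular 8-node hexahedron (2x2x2 Gauss)."""
    C = _elastic_C(material.E, material.nu)
    hx, hy, hz = h
    jac = np.array([hx / 2, hy / 2, hz / 2])
    detj = np.prod(jac)
    Ke = np.zeros((24, 24))
    gp = np.array([-1.0, 1.0]) / np.sqrt(3.0)
    for xi in gp:
        for eta in gp:
            for zeta in gp:
                g_nat = _shape_grad(np.array([xi, eta, zeta]))
                g_xyz = g_nat / jac  # diagonal Jacobian
                B = _b_matrix(g_xyz)
                Ke += B.T @ C @ B * detj
    return Ke


# ---------------------------------------------------------------------------
# mesh


@dataclass
class VoxelMesh:
    """Voxel element mesh on the full node grid of a label volume."""

    shape: tuple[int, int, int]  # elements per axis
    spacing: tuple[float, float, float]  # um
    conn: np.ndarray  # (ne, 8) int32 node ids of active elements
    mat_id: np.ndarray  # (ne,) int8: 0 bone, 1 canal phase
    elem_index: np.ndarray  # (ne, 3) integer element coordinates
    active_nodes: np.ndarray  # bool per node

    @property
    def n_nodes(self) -> int:
        nx, ny, nz = self.shape
        return (nx + 1) * (ny + 1) * (nz + 1)

    @property
    def ndof(self) -> int:
        return 3 * self.n_nodes

    def node_grid_shape(self) -> tuple[int, int, int]:
        nx, ny, nz = self.shape
        return (nx + 1, ny + 1, nz + 1)

    def node_coords_um(self) -> np.ndarray:
        gx, gy, gz = self.node_grid_shape()
        sx, sy, sz = self.spacing
        X, Y, Z = np.meshgrid(
            np.arange(gx) * sx, np.arange(gy) * sy, np.arange(gz) * sz, indexing="ij"
        )
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def _downsample_labels(labels: np.ndarray, f: int) -> np.ndarray:
    nx, ny, nz = (s // f for s in labels.shape)
    lab = labels[: nx * f, : ny * f, : nz * f]
    blocks = lab.reshape(nx, f, ny, f, nz, f)
    counts = np.stack(
        [(blocks == code).sum(axis=(1, 3, 5)) for code in (BACKGROUND, BONE, CANAL)], axis=-1
    )
    return np.argmax(counts, axis=-1).astype(np.uint8)


def assign_materials(
    label: LabelVolume,
    spec: MaterialSpec,
    scenario: str,
    downsample: int = 1,
    min_element_um: float | None = None,
) -> tuple[VoxelMesh, list[Material]]:
    """Build the element mesh and per-element materials for a scenario.

    One element per voxel, optionally coarsened by an integer factor with
    per-block majority vote.  Background voxels are allowed only as
    boundary padding (their connected component must touch the volume
    boundary); interior background is a modelling error.  If
    ``min_element_um`` is given (the certified imaging resolution), an
    element edge below it is rejected.
    """
    labels = label.labels
    spacing = np.asarray(label.spacing, dtype=float)
    if downsample > 1:
        labels = _downsample_labels(labels, downsample)
        spacing = spacing * downsample
    if min_element_um is not None and np.any(spacing < min_element_um - 1e-9):
        raise ValueError(
            f"element size {tuple(spacing)} um is below the imaging resolution "
            f"{min_element_um} um; increase the downsample factor"
        )
    bg = labels == BACKGROUND
    if bg.any():
        from scipy import ndimage

        lab_bg, n_bg = ndimage.label(bg)
        border = np.zeros_like(bg)
        border[[0, -1], :, :] = True
        border[:, [0, -1], :] = True
        border[:, :, [0, -1]] = True
        touching = np.unique(lab_bg[border & bg])
        interior = np.setdiff1d(np.arange(1, n_bg + 1), touching)
        if interior.size:
            raise ValueError(
                f"{interior.size} interior background component(s): the FE domain "
                "would be non-manifold; fill or crop them"
            )
    nx, ny, nz = labels.shape
    active = labels != BACKGROUND
    ei = np.argwhere(active).astype(np.int64)
    nyp, nzp = ny + 1, nz + 1

    def nid(i, j, k):
        return (i * nyp + j) * nzp + k

    i, j, k = ei[:, 0], ei[:, 1], ei[:, 2]
    conn = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    ).astype(np.int64)
    mat_id = (labels[tuple(ei.T)] == CANAL).astype(np.int8)
    canal_mat = spec.canal_material(scenario)
    materials = [spec.bone, canal_mat]
    active_nodes = np.zeros((nx + 1) * nyp * nzp, dtype=bool)
    active_nodes[conn.ravel()] = True
    mesh = VoxelMesh(
        shape=(nx, ny, nz),
        spacing=tuple(spacing),
        conn=conn,
        mat_id=mat_id,
        elem_index=ei,
        active_nodes=active_nodes,
    )
    return mesh, materials


# ---------------------------------------------------------------------------
# numba kernels


@numba.njit(cache=True, fastmath=True)
def _matvec_kernel(u, out, conn, mat, kes, fixed):
    out[:] = 0.0
    ue = np.empty(24)
    fe = np.empty(24)
    for e in range(conn.shape[0]):
        ke = kes[mat[e]]
        for a in range(8):
            n3 = 3 * conn[e, a]
            a3 = 3 * a
            for c in range(3):
                d = n3 + c
                ue[a3 + c] = 0.0 if fixed[d] else u[d]
        for i in range(24):
            s = 0.0
            for j in range(24):
                s += ke[i, j] * ue[j]
            fe[i] = s
        for a in range(8):
            n3 = 3 * conn[e, a]
            a3 = 3 * a
            for c in range(3):
                out[n3 + c] += fe[a3 + c]
    for d in range(out.shape[0]):
        if fixed[d]:
            out[d] = 0.0


@numba.njit(cache=True, fastmath=True)
def _full_matvec_kernel(u, out, conn, mat, kes):
    out[:] = 0.0
    ue = np.empty(24)
    fe = np.empty(24)
    for e in range(conn.shape[0]):
        ke = kes[mat[e]]
        for a in range(8):
            n3 = 3 * conn[e, a]
            a3 = 3 * a
            for c in range(3):
                ue[a3 + c] = u[n3 + c]
        for i in range(24):
            s = 0.0
            for j in range(24):
                s += ke[i, j] * ue[j]
            fe[i] = s
        for a in range(8):
            n3 = 3 * conn[e, a]
            a3 = 3 * a
            for c in range(3):
                out[n3 + c] += fe[a3 + c]


@numba.njit(cache=True, fastmath=True)
def _diag_blocks_kernel(conn, mat, kes, blocks):
    for e in range(conn.shape[0]):
        ke = kes[mat[e]]
        for a in range(8):
            n = conn[e, a]
            a3 = 3 * a
            for r in range(3):
                for c in range(3):
                    blocks[n, r, c] += ke[a3 + r, a3 + c]


class _Operator:
    """Matrix-free projected stiffness operator with block-Jacobi precond."""

    def __init__(self, mesh: VoxelMesh, materials: list[Material]):
        self.mesh = mesh
        kes = np.stack([hex_stiffness(m, mesh.spacing) for m in materials])
        self.kes = np.ascontiguousarray(kes)
        self.conn = np.ascontiguousarray(mesh.conn)
        self.mat = np.ascontiguousarray(mesh.mat_id)
        self.ndof = mesh.ndof

    def full_matvec(self, u: np.ndarray) -> np.ndarray:
        out = np.empty(self.ndof)
        _full_matvec_kernel(u, out, self.conn, self.mat, self.kes)
        return out

    def projected_matvec(self, u: np.ndarray, fixed: np.ndarray) -> np.ndarray:
        out = np.empty(self.ndof)
        _matvec_kernel(u, out, self.conn, self.mat, self.kes, fixed)
        return out

    def block_jacobi(self, fixed: np.ndarray) -> np.ndarray:
        blocks = np.zeros((self.mesh.n_nodes, 3, 3))
        _diag_blocks_kernel(self.conn, self.mat, self.kes, blocks)
        # free-free restriction per node: zero rows/cols of fixed dofs
        free3 = (~fixed.reshape(-1, 3)).astype(float)
        mask = free3[:, :, None] * free3[:, None, :]
        B = blocks * mask
        diag = np.arange(3)
        B[:, diag, diag] = np.where(free3 == 1.0, B[:, diag, diag], 1.0)
        B[~self.mesh.active_nodes] = np.eye(3)
        return np.linalg.inv(B)


def _pcg(
    op: _Operator,
    fixed: np.ndarray,
    u_bc: np.ndarray,
    x0: np.ndarray | None,
    tol: float,
    maxiter: int,
) -> tuple[np.ndarray, list[float]]:
    """Solve K u = 0 subject to Dirichlet values in u_bc on `fixed` dofs."""
    ndof = op.ndof
    # inactive (dangling) node dofs are pinned to zero
    fixed = fixed.copy()
    fixed[np.repeat(~op.mesh.active_nodes, 3)] = True
    # rhs = -P K u_bc
    ku = op.full_matvec(u_bc * fixed)
    rhs = -ku
    rhs[fixed] = 0.0
    Minv = op.block_jacobi(fixed)

    def apply_prec(r):
        return np.einsum("nij,nj->ni", Minv, r.reshape(-1, 3)).ravel()

    x = np.zeros(ndof) if x0 is None else x0.copy()
    x[fixed] = 0.0
    r = rhs - op.projected_matvec(x, fixed)
    z = apply_prec(r)
    p = z.copy()
    rz = float(r @ z)
    norm0 = float(np.linalg.norm(rhs))
    history: list[float] = []
    if norm0 == 0.0:
        return u_bc * fixed + x, history
    for it in range(maxiter):
        Ap = op.projected_matvec(p, fixed)
        pAp = float(p @ Ap)
        if pAp <= 0:
            break
        alpha = rz / pAp
        x += alpha * p
        r -= alpha * Ap
        rn = float(np.linalg.norm(r))
        history.append(rn / norm0)
        if rn / norm0 < tol:
            break
        z = apply_prec(r)
        rz_new = float(r @ z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    else:
        raise RuntimeError(
            f"PCG did not converge in {maxiter} iterations; "
            f"relative residual history tail: {history[-5:]}"
        )
    u = x.copy()
    u[fixed] = 0.0
    u += u_bc * fixed
    return u, history


# ---------------------------------------------------------------------------
# boundary conditions

_AX = {"x": 0, "y": 1, "z": 2}


def _node_index_grids(mesh: VoxelMesh):
    gx, gy, gz = mesh.node_grid_shape()
    return np.meshgrid(np.arange(gx), np.arange(gy), np.arange(gz), indexing="ij")


def _face_node_ids(mesh: VoxelMesh, axis: int, end: int) -> np.ndarray:
    gx, gy, gz = mesh.node_grid_shape()
    gshape = (gx, gy, gz)
    ids = np.arange(mesh.n_nodes).reshape(gshape)
    sl = [slice(None)] * 3
    sl[axis] = -1 if end else 0
    return ids[tuple(sl)].ravel()


def _build_bc(
    mesh: VoxelMesh, case: LoadCase, bc_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet mask and values for a load case.

    Uniaxial (``bc_mode='paper'``): both faces normal to the loading axis
    act as rollers (normal displacement 0 at the bottom, applied at the
    top), lateral faces free, rigid-body motion pinned at corner nodes —
    the configuration that leaves a homogeneous bar in exact uniaxial
    stress.  Shear: the affine simple-shear field is prescribed on the
    entire boundary (a kinematic-uniform condition; with free lateral
    faces a finite block under-reads G through edge effects).
    ``bc_mode='kubc'`` prescribes the affine field on the whole boundary
    for uniaxial cases too.
    """
    ndof = mesh.ndof
    fixed = np.zeros(ndof, dtype=bool)
    ubc = np.zeros(ndof)
    coords = mesh.node_coords_um()
    L = np.array(mesh.shape) * np.array(mesh.spacing)
    eps = case.applied_strain
    boundary = np.zeros(mesh.n_nodes, dtype=bool)
    for ax in range(3):
        boundary[_face_node_ids(mesh, ax, 0)] = True
        boundary[_face_node_ids(mesh, ax, 1)] = True

    if case.kind == "uniaxial":
        a = _AX[case.axis]
        if bc_mode == "kubc":
            # classical kinematic-uniform BC: affine field on the whole boundary
            bidx = np.nonzero(boundary)[0]
            for c in range(3):
                fixed[bidx * 3 + c] = True
            ubc[bidx * 3 + a] = eps * coords[bidx, a]
        else:
            bot = _face_node_ids(mesh, a, 0)
            top = _face_node_ids(mesh, a, 1)
            fixed[bot * 3 + a] = True
            fixed[top * 3 + a] = True
            ubc[top * 3 + a] = eps * L[a]
            # pin the in-plane rigid modes (two translations + one rotation)
            b, c = [ax for ax in range(3) if ax != a]
            origin = np.zeros(3)
            n0 = _nearest_node(mesh, coords, origin)
            fixed[n0 * 3 + b] = True
            fixed[n0 * 3 + c] = True
            pb = origin.copy()
            pb[b] = L[b]
            n1 = _nearest_node(mesh, coords, pb)
            fixed[n1 * 3 + c] = True
    else:
        a, b = _AX[case.axis[0]], _AX[case.axis[1]]
        bidx = np.nonzero(boundary)[0]
        for c in range(3):
            fixed[bidx * 3 + c] = True
        ubc[bidx * 3 + a] = eps * coords[bidx, b]
    return fixed, ubc


def _nearest_node(mesh: VoxelMesh, coords: np.ndarray, point: np.ndarray) -> int:
    ok = np.nonzero(mesh.active_nodes)[0]
    return int(ok[np.argmin(((coords[ok] - point) ** 2).sum(axis=1))])


# ---------------------------------------------------------------------------
# solving and post-processing


def solve_case(
    mesh: VoxelMesh,
    materials: list[Material],
    case: LoadCase,
    tol: float = 1e-8,
    maxiter: int = 6000,
    bc_mode: str = "paper",
    x0: np.ndarray | None = None,
    coarse_init: bool = True,
) -> np.ndarray:
    """Solve one load case; returns the nodal displacement field (um)."""
    op = _Operator(mesh, materials)
    fixed, ubc = _build_bc(mesh, case, bc_mode)
    if x0 is None:
        x0 = _initial_guess(mesh, materials, case, bc_mode, fixed, ubc, tol, coarse_init)
    u, _ = _pcg(op, fixed, ubc, x0, tol, maxiter)
    return u


def _affine_guess(mesh: VoxelMesh, materials: list[Material], case: LoadCase) -> np.ndarray:
    """Uniform-strain displacement field matching the case kinematics."""
    coords = mesh.node_coords_um()
    eps = case.applied_strain
    u = np.zeros((mesh.n_nodes, 3))
    if case.kind == "uniaxial":
        a = _AX[case.axis]
        nu = materials[0].nu
        u[:, a] = eps * coords[:, a]
        for c in range(3):
            if c != a:
                u[:, c] = -nu * eps * coords[:, c]
    else:
        a, b = _AX[case.axis[0]], _AX[case.axis[1]]
        u[:, a] = eps * coords[:, b]
    return u.ravel()


def _initial_guess(mesh, materials, case, bc_mode, fixed, ubc, tol, coarse_init):
    guess = _affine_guess(mesh, materials, case)
    guess = guess - ubc * fixed  # _pcg solves for the free-dof correction
    guess[fixed] = 0.0
    if not coarse_init or min(mesh.shape) < 8 or any(s % 2 for s in mesh.shape):
        return guess
    # cascadic start: solve the factor-2-coarsened problem and prolong
    coarse_labels = _downsample_labels(_labels_from_mesh(mesh), 2)
    coarse = LabelVolume(
        coarse_labels, tuple(2 * s for s in mesh.spacing)
    )
    cmesh = VoxelMesh(
        shape=coarse_labels.shape,
        spacing=tuple(2 * s for s in mesh.spacing),
        **_mesh_arrays(coarse_labels),
    )
    cmats = materials
    uc = solve_case(
        cmesh, cmats, case, tol=max(tol, 1e-6), maxiter=4000, bc_mode=bc_mode,
        coarse_init=min(cmesh.shape) >= 16,
    )
    uf = _prolong(uc, cmesh, mesh)
    uf = uf - ubc * fixed
    uf[fixed] = 0.0
    return uf


def _labels_from_mesh(mesh: VoxelMesh) -> np.ndarray:
    labels = np.zeros(mesh.shape, dtype=np.uint8)
    ei = mesh.elem_index
    labels[ei[:, 0], ei[:, 1], ei[:, 2]] = np.where(mesh.mat_id == 1, CANAL, BONE)
    return labels


def _mesh_arrays(labels: np.ndarray) -> dict:
    nx, ny, nz = labels.shape
    nyp, nzp = ny + 1, nz + 1
    ei = np.argwhere(labels != BACKGROUND).astype(np.int64)
    i, j, k = ei[:, 0], ei[:, 1], ei[:, 2]

    def nid(i_, j_, k_):
        return (i_ * nyp + j_) * nzp + k_

    conn = np.stack(
        [
            nid(i, j, k),
            nid(i + 1, j, k),
            nid(i + 1, j + 1, k),
            nid(i, j + 1, k),
            nid(i, j, k + 1),
            nid(i + 1, j, k + 1),
            nid(i + 1, j + 1, k + 1),
            nid(i, j + 1, k + 1),
        ],
        axis=1,
    ).astype(np.int64)
    active_nodes = np.zeros((nx + 1) * nyp * nzp, dtype=bool)
    active_nodes[conn.ravel()] = True
    return dict(
        conn=conn,
        mat_id=(labels[tuple(ei.T)] == CANAL).astype(np.int8),
        elem_index=ei,
        active_nodes=active_nodes,
    )


def _prolong(uc: np.ndarray, cmesh: VoxelMesh, fmesh: VoxelMesh) -> np.ndarray:
    from scipy.interpolate import RegularGridInterpolator

    cg = cmesh.node_grid_shape()
    fg = fmesh.node_grid_shape()
    ucg = uc.reshape(*cg, 3)
    axes_c = [np.arange(n) * 2.0 for n in cg]
    pts = np.meshgrid(*[np.arange(n, dtype=float) for n in fg], indexing="ij")
    pts = np.stack([p.ravel() for p in pts], axis=1)
    np.clip(pts[:, 0], 0, axes_c[0][-1], out=pts[:, 0])
    np.clip(pts[:, 1], 0, axes_c[1][-1], out=pts[:, 1])
    np.clip(pts[:, 2], 0, axes_c[2][-1], out=pts[:, 2])
    out = np.empty((pts.shape[0], 3))
    for c in range(3):
        interp = RegularGridInterpolator(axes_c, ucg[..., c])
        out[:, c] = interp(pts)
    return out.ravel()


@dataclass
class StressField:
    """Per-element stresses (GPa): 6 Voigt components, von Mises, principal."""

    sigma: np.ndarray  # (ne, 6): xx, yy, zz, xy, yz, zx
    von_mises: np.ndarray  # (ne,)
    principal: np.ndarray  # (ne, 3) descending


def element_stresses(
    u: np.ndarray, mesh: VoxelMesh, materials: list[Material]
) -> StressField:
    """Centroid stresses from the displacement field."""
    g_nat = _shape_grad(np.zeros(3))
    jac = np.array(mesh.spacing) / 2.0
    B = _b_matrix(g_nat / jac)
    ue = u.reshape(-1, 3)[mesh.conn].reshape(len(mesh.conn), 24)
    strain = ue @ B.T
    sigma = np.empty_like(strain)
    for m, mat in enumerate(materials):
        sel = mesh.mat_id == m
        if sel.any():
            C = _elastic_C(mat.E, mat.nu)
            sigma[sel] = strain[sel] @ C.T
    sxx, syy, szz, sxy, syz, szx = sigma.T
    T = np.zeros((len(sigma), 3, 3))
    T[:, 0, 0], T[:, 1, 1], T[:, 2, 2] = sxx, syy, szz
    T[:, 0, 1] = T[:, 1, 0] = sxy
    T[:, 1, 2] = T[:, 2, 1] = syz
    T[:, 0, 2] = T[:, 2, 0] = szx
    principal = np.linalg.eigvalsh(T)[:, ::-1]
    s1, s2, s3 = principal.T
    vm = np.sqrt(((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2) / 2.0)
    return StressField(sigma=sigma, von_mises=vm, principal=principal)


# ---------------------------------------------------------------------------
# homogenization


@dataclass
class EngineeringConstants:
    """Homogenised orthotropic constants in cylindrical axes (r=x, t=theta=y, z)."""

    E_r: float
    E_t: float
    E_z: float
    G_rt: float
    G_tz: float
    G_rz: float
    nu_rt: float
    nu_rz: float
    nu_tz: float
    # minor ratios (reciprocity partners nu_ji = nu_ij E_j / E_i)
    nu_tr: float = float("nan")
    nu_zr: float = float("nan")
    nu_zt: float = float("nan")
    mean_density: float = float("nan")
    porosity: float = float("nan")
    geometry_hash: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            "E_r [GPa]": self.E_r,
            "E_theta [GPa]": self.E_t,
            "E_z [GPa]": self.E_z,
            "G_rtheta [GPa]": self.G_rt,
            "G_thetaz [GPa]": self.G_tz,
            "G_rz [GPa]": self.G_rz,
            "nu_rtheta [-]": self.nu_rt,
            "nu_rz [-]": self.nu_rz,
            "nu_thetaz [-]": self.nu_tz,
            "nu_thetar [-]": self.nu_tr,
            "nu_zr [-]": self.nu_zr,
            "nu_ztheta [-]": self.nu_zt,
            "mean_density [g/cm^3]": self.mean_density,
            "porosity [fraction]": self.porosity,
        }


def _geometry_hash(label: LabelVolume) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(label.labels).tobytes())
    h.update(repr(label.spacing).encode())
    return h.hexdigest()[:16]


def _face_reaction(
    op: _Operator, u: np.ndarray, mesh: VoxelMesh, axis: int, comp: int
) -> float:
    f = op.full_matvec(u)
    ids = _face_node_ids(mesh, axis, 1)
    return float(f.reshape(-1, 3)[ids, comp].sum())


def _face_area_um2(mesh: VoxelMesh, axis: int) -> float:
    # area of active elements on the max face
    sl = mesh.elem_index[:, axis] == mesh.shape[axis] - 1
    s = [mesh.spacing[c] for c in range(3) if c != axis]
    return float(np.count_nonzero(sl) * s[0] * s[1])


def homogenize(
    label: LabelVolume,
    spec: MaterialSpec,
    scenario: str,
    strain: float = 0.02,
    tol: float = 1e-8,
    bc_mode: str = "paper",
    downsample: int = 1,
    min_element_um: float | None = None,
    coarse_init: bool = True,
    warm_start: dict[tuple[str, str], np.ndarray] | None = None,
    return_fields: bool = False,
) -> EngineeringConstants | tuple[EngineeringConstants, dict]:
    """Effective engineering constants from six prescribed-strain cases.

    Three uniaxial cases give E_i from the reaction force on the
    prescribed face divided by face area and strain, and nu_ij from the
    mean relative displacement of the lateral face pairs; three shear
    cases give G_ij from the tangential reaction on the driven face.
    Axes are relabeled cylindrically (x->r, y->theta, z->z).

    ``warm_start`` maps case keys ``(kind, axis)`` to displacement fields
    from a previous scenario on the same mesh (they make excellent
    initial guesses); with ``return_fields=True`` the solved fields are
    returned alongside the constants for exactly that purpose.
    """
    mesh, materials = assign_materials(
        label, spec, scenario, downsample=downsample, min_element_um=min_element_um
    )
    op = _Operator(mesh, materials)
    L = np.array(mesh.shape) * np.array(mesh.spacing)
    fields: dict[tuple[str, str], np.ndarray] = {}

    def _solve(case: LoadCase) -> np.ndarray:
        key = (case.kind, case.axis)
        x0 = None
        if warm_start is not None and key in warm_start:
            fixed, ubc = _build_bc(mesh, case, bc_mode)
            x0 = warm_start[key] - ubc * fixed
            x0[fixed] = 0.0
        u = solve_case(
            mesh, materials, case, tol=tol, bc_mode=bc_mode, x0=x0, coarse_init=coarse_init
        )
        fields[key] = u
        return u

    E = {}
    nu = {}
    for axis in ("x", "y", "z"):
        case = LoadCase(kind="uniaxial", axis=axis, applied_strain=strain)
        u = _solve(case)
        a = _AX[axis]
        F = _face_reaction(op, u, mesh, a, a)
        E[axis] = F / (_face_area_um2(mesh, a) * strain)
        un = u.reshape(-1, 3)
        for lat in range(3):
            if lat == a:
                continue
            lo = un[_face_node_ids(mesh, lat, 0), lat].mean()
            hi = un[_face_node_ids(mesh, lat, 1), lat].mean()
            nu[(a, lat)] = -((hi - lo) / L[lat]) / strain
    G = {}
    for plane in ("xy", "yz", "zx"):
        case = LoadCase(kind="shear", axis=plane, applied_strain=strain)
        u = _solve(case)
        a, b = _AX[plane[0]], _AX[plane[1]]
        F = _face_reaction(op, u, mesh, b, a)
        G[plane] = F / (_face_area_um2(mesh, b) * strain)
    phi = float(np.mean(mesh.mat_id == 1))
    ec = EngineeringConstants(
        E_r=E["x"],
        E_t=E["y"],
        E_z=E["z"],
        G_rt=G["xy"],
        G_tz=G["yz"],
        G_rz=G["zx"],
        nu_rt=nu[(0, 1)],
        nu_rz=nu[(0, 2)],
        nu_tz=nu[(1, 2)],
        nu_tr=nu[(1, 0)],
        nu_zr=nu[(2, 0)],
        nu_zt=nu[(2, 1)],
        mean_density=mean_density(label, spec, scenario),
        porosity=phi,
        geometry_hash=_geometry_hash(label),
    )
    return (ec, fields) if return_fields else ec


def mean_density(label: LabelVolume, spec: MaterialSpec, scenario: str) -> float:
    """Volume-fraction-weighted mean density (g/cm^3), background excluded."""
    canal = np.count_nonzero(label.labels == CANAL)
    bone = np.count_nonzero(label.labels == BONE)
    if canal + bone == 0:
        raise ValueError("no tissue voxels")
    phi = canal / (canal + bone)
    return float((1 - phi) * spec.bone.rho + phi * spec.canal_material(scenario).rho)


def voigt_modulus(E1: float, E2: float, f2: float) -> float:
    """Arithmetic-mean (upper-bound) modulus of a two-phase composite."""
    return (1 - f2) * E1 + f2 * E2


def reuss_modulus(E1: float, E2: float, f2: float) -> float:
    """Harmonic-mean (lower-bound) modulus of a two-phase composite."""
    return 1.0 / ((1 - f2) / E1 + f2 / E2)
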