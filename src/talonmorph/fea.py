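"""Linear-elastic finite-element analysis on 4-node tetrahedra.

Small-strain isotropic elasticity with constant-strain tetrahedral
elements, for the scale-free comparative grip-loading protocol: every
model is first scaled to a common reference surface area
(k = sqrt(SA_ref / SA_model) on linear dimensions), restrained at the
talon tip and at the two cotyla apices, and loaded with the per-digit
share of a fixed total grip force split over the medial and lateral
flexor-tubercle patches along -z.

Default material is cortical bone (E = 21,100 MPa, nu = 0.32); the
stiffened-patch option couples patch nodes through a truss network with
structural-steel modulus (200,000 MPa) to emulate load-spreading cages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TetMesh

BONE = None  # set below


@dataclass(frozen=True)
class ElasticMaterial:
    """Isotropic linear-elastic material (moduli in MPa)."""

    youngs_modulus: float = 21_100.0
    poisson_ratio: float = 0.32

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("Young's modulus must be > 0")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ValueError("Poisson's ratio must be in (0, 0.5)")

    def d_matrix(self) -> np.ndarray:
        """6x6 constitutive matrix, Voigt order (xx, yy, zz, xy, yz, zx)."""
        e, nu = self.youngs_modulus, self.poisson_ratio
        lam = e * nu / ((1 + nu) * (1 - 2 * nu))
        mu = e / (2 * (1 + nu))
        d = np.zeros((6, 6))
        d[:3, :3] = lam
        d[np.diag_indices(3)] = lam + 2 * mu
        d[3:, 3:] = mu * np.eye(3)
        return d


BONE = ElasticMaterial(21_100.0, 0.32)
STEEL = ElasticMaterial(200_000.0, 0.30)


@dataclass
class LoadCase:
    """Restraints and loads expressed on named node sets.

    ``restraints``: (node_set, axes) with axes a subset of "xyz" — those
    translational DOFs are fixed. ``loads``: (node_set, force vector in N)
    distributed uniformly over the set's nodes. ``total_grip_force`` and
    ``n_digits`` document the protocol the loads came from.
    """

    restraints: list[tuple[str, str]]
    loads: list[tuple[str, np.ndarray]]
    total_grip_force: float = 9.77
    n_digits: int = 4
    stiff_patch: bool = False


def grip_load_case(total_grip_force: float = 9.77, n_digits: int = 4,
                   stiff_patch: bool = False) -> LoadCase:
    """The comparative protocol: tip and both cotyla apices fixed in
    translation; the single-digit share of the grip force split equally
    between the medial and lateral tubercle patches, along -z."""
    per_digit = total_grip_force / n_digits
    per_patch = per_digit / 2.0
    fvec = np.array([0.0, 0.0, -per_patch])
    return LoadCase(
        restraints=[("tip", "xyz"), ("cotyla_medial", "xyz"),
                    ("cotyla_lateral", "xyz")],
        loads=[("tubercle_medial", fvec), ("tubercle_lateral", fvec)],
        total_grip_force=total_grip_force, n_digits=n_digits,
        stiff_patch=stiff_patch)


@dataclass
class FEField:
    """Solution of one load case."""

    displacements: np.ndarray          # (n_nodes, 3) mm
    element_stress: np.ndarray         # (n_tets, 6) Voigt MPa
    vm_stress: np.ndarray              # (n_tets,) MPa
    reactions: np.ndarray              # (n_nodes, 3) N at restrained DOFs


@dataclass(frozen=True)
class ScalingSpec:
    reference_surface_area: float
    model_surface_area: float
    k: float


def scale_to_reference_area(mesh: TetMesh, reference_area: float,
                            literal_formula: bool = False
                            ) -> tuple[TetMesh, ScalingSpec]:
    """Scale a model so its external surface area equals the reference.

    The scale factor is k = sqrt(SA_ref / SA_model) on linear dimensions
    (areas scale as k^2). ``literal_formula`` instead applies the printed
    but dimensionally inconsistent k = sqrt(SA_model) / SA_ref, kept for
    archaeology only.
    """
    area = mesh.surface_area()
    if area <= 0 or reference_area <= 0:
        raise ValueError("surface areas must be positive")
    if literal_formula:
        k = np.sqrt(area) / reference_area
    else:
        k = float(np.sqrt(reference_area / area))
    return mesh.scaled(k), ScalingSpec(reference_area, area, k)


# ---------------------------------------------------------------- assembly

def _element_b_matrices(mesh: TetMesh) -> tuple[np.ndarray, np.ndarray]:
    """Per-element strain-displacement matrices B (T, 6, 12) and volumes."""
    p = mesh.nodes[mesh.tets]                       # (T, 4, 3)
    m = p[:, 1:] - p[:, :1]                         # (T, 3, 3) edge matrix
    det = np.linalg.det(m)
    vol = det / 6.0
    if (vol <= 0).any():
        bad = int(np.argmax(vol <= 0))
        raise ValueError(f"inverted element {bad} (volume {vol[bad]:.3g})")
    minv = np.linalg.inv(m)                         # rows: d(lam_i)/dx
    grads = np.empty((len(p), 4, 3))
    grads[:, 1:] = np.transpose(minv, (0, 2, 1))
    grads[:, 0] = -grads[:, 1:].sum(axis=1)

    B = np.zeros((len(p), 6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a, 0], grads[:, a, 1], grads[:, a, 2]
        c = 3 * a
        B[:, 0, c] = gx
        B[:, 1, c + 1] = gy
        B[:, 2, c + 2] = gz
        B[:, 3, c] = gy
        B[:, 3, c + 1] = gx
        B[:, 4, c + 1] = gz
        B[:, 4, c + 2] = gy
        B[:, 5, c] = gz
        B[:, 5, c + 2] = gx
    return B, vol


def assemble_stiffness(mesh: TetMesh, material: ElasticMaterial) -> sp.csr_matrix:
    """Global stiffness (3N x 3N, symmetric) from constant-strain tets."""
    B, vol = _element_b_matrices(mesh)
    D = material.d_matrix()
    ke = np.einsum("tsa,sr,trb,t->tab", B, D, B, vol)   # (T, 12, 12)
    dof = (3 * mesh.tets[:, :, None] + np.arange(3)[None, None, :]).reshape(-1, 12)
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    n = 3 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def _patch_truss(mesh: TetMesh, patch: np.ndarray,
                 material: ElasticMaterial = STEEL,
                 section_area: float = 1.0) -> sp.csr_matrix | None:
    """Axial truss network linking each patch node to its two nearest
    patch neighbors (load-spreading stiffener)."""
    from scipy.spatial import cKDTree

    if len(patch) < 2:
        return None
    xyz = mesh.nodes[patch]
    k = min(3, len(patch))
    _, nn = cKDTree(xyz).query(xyz, k=k)
    pairs = {tuple(sorted((int(patch[i]), int(patch[nn[i, j]]))))
             for i in range(len(patch)) for j in range(1, k)}
    n = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    for a, b in sorted(pairs):
        d = mesh.nodes[b] - mesh.nodes[a]
        L = np.linalg.norm(d)
        if L == 0:
            continue
        u = d / L
        kax = material.youngs_modulus * section_area / L
        kmat = kax * np.outer(u, u)
        for i in range(3):
            for j in range(3):
                for (r, c, s) in ((3 * a + i, 3 * a + j, 1), (3 * b + i, 3 * b + j, 1),
                                  (3 * a + i, 3 * b + j, -1), (3 * b + i, 3 * a + j, -1)):
                    rows.append(r)
                    cols.append(c)
                    vals.append(s * kmat[i, j])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


@dataclass
class ConstrainedSystem:
    K: sp.csr_matrix                 # full stiffness
    f: np.ndarray                    # full force vector (3N,)
    free: np.ndarray                 # free DOF indices
    fixed: np.ndarray                # restrained DOF indices
    mesh: TetMesh
    material: ElasticMaterial


def apply_load_case(mesh: TetMesh, case: LoadCase,
                    material: ElasticMaterial = BONE) -> ConstrainedSystem:
    """Assemble the restrained linear system for a load case.

    Patch loads are distributed uniformly over the node set; restrained
    translational DOFs are eliminated by reduction. Raises if fewer than
    6 DOFs are constrained (rigid-body motion)."""
    ndof = 3 * mesh.n_nodes
    K = assemble_stiffness(mesh, material)
    if case.stiff_patch:
        for name, _ in case.loads:
            extra = _patch_truss(mesh, mesh.node_sets[name])
            if extra is not None:
                K = (K + extra).tocsr()

    f = np.zeros(ndof)
    for name, force in case.loads:
        nodes = mesh.node_sets[name]
        if len(nodes) == 0:
            raise ValueError(f"empty load node set {name!r}")
        per = np.asarray(force, float) / len(nodes)
        for ax in range(3):
            f[3 * nodes + ax] += per[ax]

    fixed: list[int] = []
    for name, axes in case.restraints:
        nodes = mesh.node_sets[name]
        for ax_name, ax in (("x", 0), ("y", 1), ("z", 2)):
            if ax_name in axes:
                fixed.extend(3 * nodes + ax)
    fixed_arr = np.unique(fixed)
    if len(fixed_arr) < 6:
        raise ValueError("rigid-body motion: fewer than 6 restrained DOFs")
    free = np.setdiff1d(np.arange(ndof), fixed_arr, assume_unique=True)
    return ConstrainedSystem(K, f, free, fixed_arr, mesh, material)


# ------------------------------------------------------------------ solve

def von_mises(stress_voigt: np.ndarray) -> np.ndarray:
    """Von Mises stress from Voigt (xx, yy, zz, xy, yz, zx) tensors."""
    s = np.atleast_2d(stress_voigt)
    sx, sy, sz, txy, tyz, tzx = s.T
    vm = np.sqrt(0.5 * ((sx - sy) ** 2 + (sy - sz) ** 2 + (sz - sx) ** 2)
                 + 3.0 * (txy ** 2 + tyz ** 2 + tzx ** 2))
    return vm if stress_voigt.ndim > 1 else vm[0]


def solve(system: ConstrainedSystem, method: str = "direct",
          cg_tol: float = 1e-10, cg_maxiter: int = 20000) -> FEField:
    """Solve for displacements and recover element stresses.

    ``method``: "direct" (sparse LU on the reduced SPD system) or "cg"
    (Jacobi-preconditioned conjugate gradients to relative residual
    ``cg_tol``; non-convergence raises with the residual history)."""
    K, f = system.K, system.f
    free = system.free
    Kff = K[free][:, free].tocsc()
    ff = f[free]
    u = np.zeros_like(f)
    if np.linalg.norm(ff) == 0.0:
        pass  # zero loads -> zero displacements
    elif method == "direct":
        u[free] = spla.splu(Kff).solve(ff)
    elif method == "cg":
        dinv = 1.0 / Kff.diagonal()
        M = sp.diags(dinv)
        history: list[float] = []

        def cb(xk):
            history.append(float(np.linalg.norm(ff - Kff @ xk) / np.linalg.norm(ff)))

        x, info = spla.cg(Kff, ff, rtol=cg_tol, maxiter=cg_maxiter, M=M, callback=cb)
        if info != 0:
            raise RuntimeError(
                f"CG did not converge (info={info}); residual history tail "
                f"{history[-5:]}")
        u[free] = x
    else:
        raise ValueError(f"unknown method {method!r}")

    B, _ = _element_b_matrices(system.mesh)
    ue = u.reshape(-1, 3)[system.mesh.tets].reshape(-1, 12)
    strain = np.einsum("tij,tj->ti", B, ue)
    stress = strain @ system.material.d_matrix().T
    vm = von_mises(stress)

    residual = K @ u - f
    reactions = np.zeros_like(f)
    reactions[system.fixed] = residual[system.fixed]
    return FEField(u.reshape(-1, 3), stress, vm, reactions.reshape(-1, 3))


def solve_grip(mesh: TetMesh, case: LoadCase | None = None,
               material: ElasticMaterial = BONE,
               reference_area: float | None = None) -> tuple[FEField, TetMesh]:
    """Convenience pipeline step: optionally scale to the reference area,
    then assemble and solve the grip load case. Returns the field and the
    (possibly scaled) mesh the field lives on."""
    if reference_area is not None:
        mesh, _ = scale_to_reference_area(mesh, reference_area)
    case = case or grip_load_case()
    return solve(apply_load_case(mesh, case, material)), mesh
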