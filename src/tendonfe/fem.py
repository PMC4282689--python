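"""Minimal 3D linear-elastic FE engine for 20-node hexahedra.

Provides element stiffness (reduced 2x2x2 or full 3x3x3 quadrature),
sparse assembly, Dirichlet constraints, a direct sparse solve, and
integration-point stress recovery with volume weights (IVOL) for
volume-averaged homogenisation reductions.

Small-strain linear elasticity only; engineering shear strains
(gamma = 2 eps_ij) in the 6-vector convention of :mod:`tendonfe.materials`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .elements import hex20_shape, integration_points
from .materials import Material, stiffness_of
from .mesh import Mesh, MeshError

#: Phase-modulus contrast beyond which a direct solve is flagged as
#: numerically fragile (mirrors the failure mode of homogenising a
#: 1,700 MPa fibril against a 0.1 MPa matrix).
CONTRAST_WARN_RATIO = 1e5


class SolverError(RuntimeError):
    """Singular or unacceptably ill-conditioned linear system."""


class FEMInputError(ValueError):
    """Inconsistent inputs to an FE operation."""


@dataclass
class BoundaryConditionSet:
    """Prescribed displacements and applied nodal forces.

    ``displacements``: list of (node, axis, value); ``forces``: likewise.
    A node/axis pair may not appear in both lists.
    """

    displacements: list[tuple[int, int, float]] = field(default_factory=list)
    forces: list[tuple[int, int, float]] = field(default_factory=list)
    allow_rigid_motion: bool = False

    def fix(self, node: int, axis: int, value: float = 0.0) -> None:
        self.displacements.append((int(node), int(axis), float(value)))

    def load(self, node: int, axis: int, value: float) -> None:
        self.forces.append((int(node), int(axis), float(value)))

    def validate(self) -> None:
        fixed = {(n, a) for n, a, _ in self.displacements}
        loaded = {(n, a) for n, a, _ in self.forces}
        clash = fixed & loaded
        if clash:
            raise FEMInputError(
                f"node/axis pairs with both displacement and force: {sorted(clash)[:5]}"
            )
        if len(fixed) < 6 and not self.allow_rigid_motion:
            raise FEMInputError(
                "fewer than 6 constrained dofs: rigid-body motion not eliminated "
                "(set allow_rigid_motion=True to override)"
            )


@dataclass
class IntegrationPointRecord:
    """State at one integration point (Voigt 6-vectors, engineering shear)."""

    element: int
    point: int
    stress: np.ndarray  # MPa
    strain: np.ndarray
    von_mises: float  # MPa
    ivol: float  # integration-point volume (weight x |J|)
    position: np.ndarray  # global coordinates


def _b_matrix(dNdx: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix, shape (npts, 6, 60), from global gradients.

    dNdx: (npts, 20, 3). Voigt order (11,22,33,12,13,23), engineering shear.
    """
    npts = dNdx.shape[0]
    B = np.zeros((npts, 6, 60))
    dx, dy, dz = dNdx[:, :, 0], dNdx[:, :, 1], dNdx[:, :, 2]
    B[:, 0, 0::3] = dx
    B[:, 1, 1::3] = dy
    B[:, 2, 2::3] = dz
    B[:, 3, 0::3] = dy
    B[:, 3, 1::3] = dx
    B[:, 4, 0::3] = dz
    B[:, 4, 2::3] = dx
    B[:, 5, 1::3] = dz
    B[:, 5, 2::3] = dy
    return B


def _element_kinematics(coords: np.ndarray, rule: str | int):
    """Jacobians, weights and B matrices for a batch of elements.

    coords: (E, 20, 3).  Returns (B (E,G,6,60), dV (E,G), xg (E,G,3)).
    """
    pts, wts = integration_points(rule)
    N, dN = hex20_shape(pts)  # (G,20), (G,20,3)
    J = np.einsum("gai,eaj->egij", dN, coords)  # dx_j/dxi_i
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = np.unique(np.where(detJ <= 0)[0])
        raise MeshError(f"non-positive Jacobian in element batch at {bad[:10].tolist()}")
    invJ = np.linalg.inv(J)
    # J_ij = dx_j/dxi_i, so (J^-1)_ji = dxi_i/dx_j and
    # dN_a/dx_j = sum_i dN_a/dxi_i * (J^-1)_ji
    dNdx = np.einsum("gai,egji->egaj", dN, invJ)
    E, G = coords.shape[0], pts.shape[0]
    B = np.zeros((E, G, 6, 60))
    dx, dy, dz = dNdx[..., 0], dNdx[..., 1], dNdx[..., 2]
    B[:, :, 0, 0::3] = dx
    B[:, :, 1, 1::3] = dy
    B[:, :, 2, 2::3] = dz
    B[:, :, 3, 0::3] = dy
    B[:, :, 3, 1::3] = dx
    B[:, :, 4, 0::3] = dz
    B[:, :, 4, 2::3] = dx
    B[:, :, 5, 1::3] = dz
    B[:, :, 5, 2::3] = dy
    dV = detJ * wts[None, :]
    xg = np.einsum("ga,eaj->egj", N, coords)
    return B, dV, xg


def element_stiffness(
    element_coords: np.ndarray,
    material: Material,
    integration_rule: str | int = "reduced",
) -> np.ndarray:
    """60x60 stiffness matrix of a single 20-node hexahedron.

    Reduced (2x2x2) integration matches the C3D20R element and leaves
    6 spurious zero-energy (hourglass) modes per element in addition to
    the 6 rigid-body modes; full (3x3x3) integration is rank-sufficient.
    """
    coords = np.asarray(element_coords, dtype=float).reshape(1, 20, 3)
    D = stiffness_of(material)
    B, dV, _ = _element_kinematics(coords, integration_rule)
    K = np.einsum("egia,ij,egjb,eg->ab", B, D, B, dV)
    return 0.5 * (K + K.T)


def assemble_stiffness(
    mesh: Mesh,
    materials: dict[str, Material],
    integration_rule: str | int = "reduced",
) -> sp.csr_matrix:
    """Assemble the global stiffness matrix (no constraints applied)."""
    missing = set(mesh.material_labels.tolist()) - set(materials)
    if missing:
        raise FEMInputError(f"no material supplied for labels {sorted(missing)}")
    _warn_on_contrast(materials)

    ndof = 3 * mesh.n_nodes
    rows, cols, vals = [], [], []
    labels = np.asarray(mesh.material_labels)
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.where(labels == lab)[0]
        coords = mesh.nodes[mesh.elements[idx]]
        D = stiffness_of(materials[lab])
        B, dV, _ = _element_kinematics(coords, integration_rule)
        Ke = np.einsum("egia,ij,egjb,eg->eab", B, D, B, dV)
        Ke = 0.5 * (Ke + Ke.transpose(0, 2, 1))
        edofs = (3 * mesh.elements[idx][:, :, None] + np.arange(3)).reshape(len(idx), 60)
        rows.append(np.repeat(edofs, 60, axis=1).ravel())
        cols.append(np.tile(edofs, (1, 60)).ravel())
        vals.append(Ke.ravel())
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()
    return K


def _warn_on_contrast(materials: dict[str, Material]) -> None:
    moduli = []
    for m in materials.values():
        if hasattr(m, "young_modulus"):
            moduli.append(m.young_modulus)
        else:
            moduli.extend([m.E1, m.E2, m.E3])
    if moduli and max(moduli) / min(moduli) > CONTRAST_WARN_RATIO:
        warnings.warn(
            f"phase modulus contrast {max(moduli) / min(moduli):.3g} exceeds "
            f"{CONTRAST_WARN_RATIO:.0e}; direct solve may be inaccurate "
            "(severe contrast defeated the original microstructure analysis too)",
            RuntimeWarning,
            stacklevel=3,
        )


@dataclass
class SolveResult:
    """Displacements plus diagnostics of one linear solve."""

    displacements: np.ndarray  # (n_nodes, 3)
    reactions: np.ndarray  # (n_nodes, 3), nonzero only at constrained dofs
    residual: float  # relative residual of the reduced system
    strain_energy: float
    external_work: float


def solve_system(
    K: sp.spmatrix,
    f: np.ndarray,
    bcs: BoundaryConditionSet,
) -> SolveResult:
    """Apply Dirichlet constraints to an assembled system and solve it."""
    bcs.validate()
    ndof = K.shape[0]
    f = f.copy()
    for n, a, v in bcs.forces:
        f[3 * n + a] += v
    fixed = np.array([3 * n + a for n, a, _ in bcs.displacements], dtype=np.int64)
    fixed_vals = np.array([v for _, _, v in bcs.displacements])
    if len(np.unique(fixed)) != len(fixed):
        # deduplicate identical prescriptions; conflicting ones are an error
        order = np.argsort(fixed)
        fixed, fixed_vals = fixed[order], fixed_vals[order]
        same = np.diff(fixed) == 0
        if np.any(same & (np.abs(np.diff(fixed_vals)) > 0)):
            raise FEMInputError("conflicting displacement prescriptions on a dof")
        keep = np.concatenate([[True], ~same])
        fixed, fixed_vals = fixed[keep], fixed_vals[keep]
    free = np.setdiff1d(np.arange(ndof), fixed)

    K = K.tocsr()
    Kff = K[free][:, free]
    Kfc = K[free][:, fixed]
    rhs = f[free] - Kfc @ fixed_vals

    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            uf = spla.spsolve(Kff.tocsc(), rhs)
        except (spla.MatrixRankWarning, RuntimeError) as exc:
            raise SolverError(f"singular constrained system: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("solver returned non-finite displacements")

    denom = max(np.linalg.norm(rhs), 1e-300)
    residual = float(np.linalg.norm(Kff @ uf - rhs) / denom)
    if residual > 1e-6:
        cond_est = _condition_estimate(Kff)
        raise SolverError(
            f"relative residual {residual:.3g} too large; "
            f"1-norm condition estimate {cond_est:.3g}"
        )

    u = np.zeros(ndof)
    u[fixed] = fixed_vals
    u[free] = uf
    r = K @ u - f
    reactions = np.zeros(ndof)
    reactions[fixed] = r[fixed]
    strain_energy = float(0.5 * u @ (K @ u))
    # work of the external agents: applied forces + support reactions moving
    # through their prescribed displacements
    external_work = float(0.5 * u @ f + 0.5 * fixed_vals @ reactions[fixed])
    return SolveResult(
        displacements=u.reshape(-1, 3),
        reactions=reactions.reshape(-1, 3),
        residual=residual,
        strain_energy=strain_energy,
        external_work=external_work,
    )


def _condition_estimate(K: sp.spmatrix) -> float:
    try:
        lu = spla.splu(K.tocsc())
        inv_norm = spla.onenormest(
            spla.LinearOperator(K.shape, matvec=lu.solve)
        )
        return float(spla.onenormest(K) * inv_norm)
    except Exception:
        return float("nan")


def assemble_solve(
    mesh: Mesh,
    materials: dict[str, Material],
    bcs: BoundaryConditionSet,
    integration_rule: str | int = "reduced",
) -> SolveResult:
    """Assemble the mesh stiffness, apply boundary conditions, and solve."""
    K = assemble_stiffness(mesh, materials, integration_rule)
    f = np.zeros(K.shape[0])
    return solve_system(K, f, bcs)


def von_mises(stress6: np.ndarray) -> np.ndarray:
    """Von Mises stress from Voigt vectors (...,6), order (11,22,33,12,13,23)."""
    s = np.asarray(stress6)
    s11, s22, s33 = s[..., 0], s[..., 1], s[..., 2]
    t12, t13, t23 = s[..., 3], s[..., 4], s[..., 5]
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (t12**2 + t13**2 + t23**2)
    )


def recover_stress(
    mesh: Mesh,
    displacements: np.ndarray,
    materials: dict[str, Material],
    integration_rule: str | int = "reduced",
) -> list[IntegrationPointRecord]:
    """Stress, strain, Von Mises and IVOL at every integration point."""
    u = np.asarray(displacements, dtype=float)
    if u.shape != (mesh.n_nodes, 3):
        raise FEMInputError(
            f"displacement field shape {u.shape} does not match mesh "
            f"({mesh.n_nodes} nodes)"
        )
    records: list[IntegrationPointRecord] = []
    labels = np.asarray(mesh.material_labels)
    for lab in dict.fromkeys(labels.tolist()):
        idx = np.where(labels == lab)[0]
        coords = mesh.nodes[mesh.elements[idx]]
        D = stiffness_of(materials[lab])
        B, dV, xg = _element_kinematics(coords, integration_rule)
        ue = u[mesh.elements[idx]].reshape(len(idx), 60)
        strain = np.einsum("egik,ek->egi", B, ue)
        stress = strain @ D.T
        vm = von_mises(stress)
        for ii, e in enumerate(idx):
            for g in range(B.shape[1]):
                records.append(
                    IntegrationPointRecord(
                        element=int(e),
                        point=g,
                        stress=stress[ii, g],
                        strain=strain[ii, g],
                        von_mises=float(vm[ii, g]),
                        ivol=float(dV[ii, g]),
                        position=xg[ii, g],
                    )
                )
    records.sort(key=lambda r: (r.element, r.point))
    return records


def volume_average(records: list[IntegrationPointRecord], field_selector) -> np.ndarray:
    """IVOL-weighted average of an integration-point field.

    ``field_selector`` is an attribute name (``"stress"``, ``"strain"``,
    ``"von_mises"``) or a callable mapping a record to a value.
    """
    if not records:
        raise FEMInputError("cannot volume-average an empty record list")
    if callable(field_selector):
        vals = np.array([field_selector(r) for r in records], dtype=float)
    else:
        vals = np.array([getattr(r, field_selector) for r in records], dtype=float)
    w = np.array([r.ivol for r in records])
    return np.tensordot(w, vals, axes=(0, 0)) / w.sum()
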