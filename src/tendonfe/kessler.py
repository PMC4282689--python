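"""Simplified quarter-symmetry FE model of a grasping Kessler suture repair.

Geometry (mm): the tendon quarter block spans ``[0, 3.25] x [0, 1.75] x
[0, 10]`` (full cross-section 6.5 x 3.5 mm), with the cut-end face at z = 0,
the symmetry planes at x = 0 and y = 0, and the tendon (fibril) axis along
z.  The suture is a 1D axial rod (diameter 0.2 mm, polypropylene-like,
E = 1 GPa): a longitudinal shaft from the cut face to the anchor at z = 5 mm
(half the 1 cm repair length) plus one transverse anchor segment representing
the load-transfer footprint of the grasping loop.  The rod is tied to the
tendon displacement field by penalty springs at the rod nodes: stiff normal
to the rod axis, nearly free along it (the published friction coefficient
0.005 makes axial sliding essentially frictionless; it is recorded but not
used as a Coulomb law -- the model stays linear).

Loading: an axial force on the rod where it crosses the cut face, standing
in for the mirror half pulling the suture across the laceration.  The gap
between the tendon stumps opens because the suture stretches while the
shielded stump retracts; it is measured as the mean axial displacement of
the cut-end face relative to the suture strand crossing it, which is the
face separation per repair half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .elements import hex20_shape
from .fem import (
    FEMInputError,
    SolverError,
    assemble_stiffness,
    recover_stress,
    solve_system,
    von_mises,
    BoundaryConditionSet,
)
from .materials import IsotropicElastic, Material, OrthotropicConstants
from .mesh import Mesh, box_mesh

TENDON = "tendon"


class KesslerGeometryError(ValueError):
    """Suture path leaves the tendon volume or dimensions are inconsistent."""


@dataclass(frozen=True)
class KesslerSpec:
    """Parameters of the quarter-symmetry Kessler repair model (MPa-mm-N)."""

    half_width: float = 3.25  # mm, x extent (full width 6.5)
    half_thickness: float = 1.75  # mm, y extent (full thickness 3.5)
    length: float = 10.0  # mm, z extent
    anchor_distance: float = 5.0  # mm from cut face (half of 1 cm repair length)
    suture_diameter: float = 0.2  # mm
    suture_material: IsotropicElastic = field(
        default_factory=lambda: IsotropicElastic(1000.0, 0.4)
    )
    tendon_material: Material = field(
        default_factory=lambda: IsotropicElastic(200.0, 0.4)
    )
    friction_coefficient: float = 0.005  # recorded; tie is penalty-based
    normal_penalty: float = 1.0e3  # N/mm^2 (per unit rod length)
    tangential_factor: float = 1.0e-4  # tangential / normal penalty ratio
    anchor_stiffness_factor: float = 10.0  # anchor footprint rigidity vs EA/L
    suture_x: float | None = None  # default: third of half-width
    suture_y: float | None = None  # default: mid quarter-thickness
    divisions: tuple[int, int, int] = (10, 6, 20)
    integration_rule: str | int = "full"

    @property
    def suture_position(self) -> tuple[float, float]:
        x0 = self.half_width / 3.0 if self.suture_x is None else self.suture_x
        y0 = self.half_thickness / 2.0 if self.suture_y is None else self.suture_y
        return x0, y0

    @property
    def suture_area(self) -> float:
        return math.pi * (0.5 * self.suture_diameter) ** 2

    def validate(self) -> None:
        if min(self.half_width, self.half_thickness, self.length) <= 0:
            raise KesslerGeometryError("dimensions must be positive")
        if not (0 < self.anchor_distance < self.length):
            raise KesslerGeometryError("anchor must lie inside the model length")
        x0, y0 = self.suture_position
        if not (0 <= x0 <= self.half_width and 0 <= y0 <= self.half_thickness):
            raise KesslerGeometryError(
                f"suture path at ({x0}, {y0}) exits the tendon cross-section"
            )


@dataclass
class MacroModel:
    """Assembled quarter-symmetry repair model ready for load stepping."""

    spec: KesslerSpec
    mesh: Mesh  # tendon block
    rod_nodes: np.ndarray  # (n_rod, 3) suture path nodes
    rod_axes: np.ndarray  # (n_rod, 3) local rod axis per node (for the tie)
    stiffness: sp.csr_matrix  # tendon + rod + penalty ties
    bcs: BoundaryConditionSet
    load_dof: int  # global dof receiving the suture pull (-z)
    cut_face_nodes: np.ndarray
    _unit_solution: np.ndarray | None = None

    @property
    def n_tendon_dofs(self) -> int:
        return 3 * self.mesh.n_nodes

    @property
    def rod_end_node(self) -> int:
        return 0  # by construction the first rod node sits on the cut face

    def unit_solution(self) -> np.ndarray:
        """Displacement vector for a unit (1 N) suture pull; cached."""
        if self._unit_solution is None:
            f = np.zeros(self.stiffness.shape[0])
            f[self.load_dof] = -1.0  # pull towards the mirror half
            result = solve_system(self.stiffness, f, self.bcs)
            self._unit_solution = result.displacements.ravel()
        return self._unit_solution

    def gap_per_unit_load(self) -> float:
        """Cut-face retraction relative to the crossing suture strand, mm/N."""
        u = self.unit_solution()
        face_uz = u.reshape(-1, 3)[self.cut_face_nodes, 2].mean()
        rod_uz = u[self.n_tendon_dofs + 3 * self.rod_end_node + 2]
        return float(face_uz - rod_uz)


def _locate_in_grid(spec: KesslerSpec, point: np.ndarray) -> tuple[int, np.ndarray]:
    """(element index, local coords) of a point in the structured block."""
    nx, ny, nz = spec.divisions
    hs = np.array([spec.half_width / nx, spec.half_thickness / ny, spec.length / nz])
    idx = np.minimum((point / hs).astype(int), np.array([nx - 1, ny - 1, nz - 1]))
    centre = (idx + 0.5) * hs
    local = 2.0 * (point - centre) / hs
    e = (idx[0] * ny + idx[1]) * nz + idx[2]
    return int(e), local


def build_kessler_model(spec: KesslerSpec) -> MacroModel:
    """Mesh the tendon quarter, lay the suture rod, assemble ties and BCs."""
    spec.validate()
    mesh = box_mesh(
        (spec.half_width, spec.half_thickness, spec.length), spec.divisions,
        label=TENDON,
    )
    x0, y0 = spec.suture_position

    # rod nodes: shaft (cut face -> anchor), then transverse anchor segment
    nx, ny, nz = spec.divisions
    n_shaft = max(2, round(spec.anchor_distance / (spec.length / nz)))
    n_anchor = max(2, round(x0 / (spec.half_width / nx)))
    shaft_z = np.linspace(0.0, spec.anchor_distance, n_shaft + 1)
    shaft = np.column_stack([np.full_like(shaft_z, x0), np.full_like(shaft_z, y0), shaft_z])
    anchor_x = np.linspace(x0, 0.0, n_anchor + 1)[1:]
    anchor = np.column_stack([
        anchor_x, np.full_like(anchor_x, y0), np.full_like(anchor_x, spec.anchor_distance)
    ])
    rod_nodes = np.vstack([shaft, anchor])
    n_rod = len(rod_nodes)
    rod_elems = [(i, i + 1) for i in range(n_rod - 1)]
    axes = np.zeros((n_rod, 3))
    axes[: n_shaft + 1, 2] = 1.0  # shaft nodes slide along z
    axes[n_shaft + 1 :, 0] = 1.0  # anchor nodes slide along x

    nt = 3 * mesh.n_nodes
    ndof = nt + 3 * n_rod

    K_t = assemble_stiffness(mesh, {TENDON: spec.tendon_material}, spec.integration_rule)
    rows, cols, vals = [K_t.tocoo().row], [K_t.tocoo().col], [K_t.tocoo().data]

    # rod elements: the shaft is a plain axial truss; anchor segments form a
    # near-rigid isotropic footprint (factor x EA/L in every direction) so
    # the shaft tension turns the corner and bears along the grasping-loop
    # length -- a taut loop is transversely stiff through its tension, a
    # mechanism a linear rod cannot otherwise represent
    EA = spec.suture_material.young_modulus * spec.suture_area
    for ei, (a, b) in enumerate(rod_elems):
        d = rod_nodes[b] - rod_nodes[a]
        L = np.linalg.norm(d)
        t = d / L
        k = EA / L * (np.outer(t, t) if ei < n_shaft
                      else spec.anchor_stiffness_factor * np.eye(3))
        dofs = np.concatenate([nt + 3 * a + np.arange(3), nt + 3 * b + np.arange(3)])
        Ke = np.block([[k, -k], [-k, k]])
        rows.append(np.repeat(dofs, 6))
        cols.append(np.tile(dofs, 6))
        vals.append(Ke.ravel())

    # penalty ties: distributed collocation along each rod segment (3-point
    # Gauss per segment, rod displacement interpolated linearly), so bearing
    # pressure enters the tissue as a smooth line load rather than a set of
    # point springs
    gauss_x, gauss_w = np.polynomial.legendre.leggauss(3)
    for ei, (a, b) in enumerate(rod_elems):
        d = rod_nodes[b] - rod_nodes[a]
        L = np.linalg.norm(d)
        t = d / L
        S_dir = (np.eye(3) - np.outer(t, t)
                 + spec.tangential_factor * np.outer(t, t))
        for gx, gw in zip(gauss_x, gauss_w):
            xi = 0.5 * (gx + 1.0)  # segment coordinate in [0, 1]
            point = rod_nodes[a] + xi * d
            weight = spec.normal_penalty * L * 0.5 * gw
            S = weight * S_dir
            e, local = _locate_in_grid(spec, point)
            N, _ = hex20_shape(local)
            enodes = mesh.elements[e]
            # relative displacement: (1-xi) u_a + xi u_b - sum_c N_c u_c
            gdofs = np.concatenate([
                (3 * enodes[:, None] + np.arange(3)).ravel(),
                nt + 3 * a + np.arange(3),
                nt + 3 * b + np.arange(3),
            ])
            G = np.zeros((3, len(gdofs)))
            for c in range(20):
                G[:, 3 * c : 3 * c + 3] = -N[c] * np.eye(3)
            G[:, 60:63] = (1.0 - xi) * np.eye(3)
            G[:, 63:66] = xi * np.eye(3)
            Ke = G.T @ S @ G
            rows.append(np.repeat(gdofs, len(gdofs)))
            cols.append(np.tile(gdofs, len(gdofs)))
            vals.append(Ke.ravel())

    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(ndof, ndof),
    ).tocsr()

    bcs = BoundaryConditionSet()
    for n in mesh.nodes_on_plane(0, 0.0):
        bcs.fix(n, 0)
    for n in mesh.nodes_on_plane(1, 0.0):
        bcs.fix(n, 1)
    for n in mesh.nodes_on_plane(2, spec.length):
        bcs.fix(n, 2)
    # mirror symmetry of the transverse anchor at the x = 0 plane
    for i in range(n_rod):
        if rod_nodes[i, 0] < 1e-12:
            bcs.displacements.append((mesh.n_nodes + i, 0, 0.0))

    load_dof = nt + 3 * 0 + 2  # axial dof of the rod node on the cut face
    cut_face_nodes = mesh.nodes_on_plane(2, 0.0)
    return MacroModel(
        spec=spec,
        mesh=mesh,
        rod_nodes=rod_nodes,
        rod_axes=axes,
        stiffness=K,
        bcs=bcs,
        load_dof=load_dof,
        cut_face_nodes=cut_face_nodes,
    )


@dataclass(frozen=True)
class LoadProgram:
    """Load stepping: forces (N) or target gaps (mm), strictly increasing."""

    mode: str = "force"  # "force" | "gap"
    increments: tuple[float, ...] = (0.05, 0.1)

    def __post_init__(self) -> None:
        if self.mode not in ("force", "gap"):
            raise FEMInputError(f"unknown load mode {self.mode!r}")
        inc = np.asarray(self.increments, dtype=float)
        if len(inc) == 0 or inc[0] <= 0 or np.any(np.diff(inc) <= 0):
            raise FEMInputError("increments must be strictly increasing from 0")


@dataclass
class LoadProgramResult:
    """Per-increment solution fields and the suture force-displacement curve."""

    model: MacroModel
    forces: np.ndarray  # (n_inc,) applied suture load, N
    gaps: np.ndarray  # (n_inc,) cut-face retraction, mm
    displacements: list[np.ndarray]  # per increment, full dof vector
    curve: np.ndarray  # (n_inc, 2): suture-end displacement (mm), force (N)

    @property
    def repair_stiffness(self) -> float:
        """Slope of the (exactly linear) force-displacement curve, N/mm."""
        return float(self.forces[-1] / self.curve[-1, 0])

    def tendon_displacements(self, increment: int = -1) -> np.ndarray:
        u = self.displacements[increment]
        return u[: self.model.n_tendon_dofs].reshape(-1, 3)

    def centroid_von_mises(self, increment: int = -1) -> np.ndarray:
        """Element-centroid Von Mises stress in the tendon (suture excluded)."""
        records = recover_stress(
            self.model.mesh,
            self.tendon_displacements(increment),
            {TENDON: self.model.spec.tendon_material},
            integration_rule=1,  # single central point = element centroid
        )
        return np.array([r.von_mises for r in records])


def run_load_program(model: MacroModel, program: LoadProgram) -> LoadProgramResult:
    """Solve the (linear) model at each increment of the program."""
    u1 = model.unit_solution()
    if program.mode == "force":
        forces = np.asarray(program.increments, dtype=float)
    else:
        g1 = model.gap_per_unit_load()
        if g1 <= 0:
            raise SolverError("unit load produced a non-positive gap")
        forces = np.asarray(program.increments, dtype=float) / g1
    gaps = forces * model.gap_per_unit_load()
    displacements = [F * u1 for F in forces]
    end_dof = model.n_tendon_dofs + 3 * model.rod_end_node + 2
    curve = np.column_stack([-forces * u1[end_dof], forces])
    return LoadProgramResult(
        model=model, forces=forces, gaps=gaps,
        displacements=displacements, curve=curve,
    )


@dataclass
class StressRegionMetrics:
    """Shape metrics of the high-stress region around the suture anchor."""

    peak_von_mises: float  # MPa, max element-centroid value
    aspect_ratio: float  # longitudinal / transverse extent of the >=50% region
    shielded: bool  # cut-end slab below 25% of the model mean
    slab_mean: float  # mean Von Mises within 1 mm of the cut face, MPa
    model_mean: float  # mean Von Mises over all tendon elements, MPa


def stress_region_metrics(
    vm_centroid: np.ndarray,
    mesh: Mesh,
    shaft_xy: tuple[float, float] | None = None,
    exclusion_radius: float = 0.5,
    slab_depth: float = 1.0,
    level: float = 0.5,
) -> StressRegionMetrics:
    """Characterise the stress field from element-centroid Von Mises values.

    The high-stress region collects elements at or above ``level`` x peak.
    Its extents are measured as exceedance-weighted RMS widths
    ``sqrt(12 Var_i)`` of the member centroids (weights ``vm - level*peak``),
    which equal the min/max extents for a uniform region but stay smooth on
    coarse meshes where a hard bounding box jumps by whole elements.  The
    aspect ratio is the longitudinal (z) extent over the larger transverse
    extent.  The shielded-zone statistic averages the slab within
    ``slab_depth`` of the cut face, excluding elements within
    ``exclusion_radius`` of the suture shaft when its position is given.
    """
    vm = np.asarray(vm_centroid, dtype=float)
    if vm.size == 0 or vm.size != mesh.n_elements:
        raise FEMInputError("need one centroid Von Mises value per element")
    cent = mesh.element_centroids()
    peak = float(vm.max())
    if peak <= 0:
        raise FEMInputError("stress field is identically zero")
    mask = vm >= level * peak
    region = cent[mask]
    w = vm[mask] - level * peak
    if w.sum() <= 0:  # flat field at exactly the level: uniform weights
        w = np.ones(len(region))
    mean = np.average(region, axis=0, weights=w)
    var = np.average((region - mean) ** 2, axis=0, weights=w)
    ext = np.maximum(np.sqrt(12.0 * var), 1e-12)
    aspect = float(ext[2] / max(ext[0], ext[1]))

    z0 = mesh.nodes[:, 2].min()
    slab = cent[:, 2] <= z0 + slab_depth
    if shaft_xy is not None:
        r = np.hypot(cent[:, 0] - shaft_xy[0], cent[:, 1] - shaft_xy[1])
        slab &= r > exclusion_radius
    slab_mean = float(vm[slab].mean()) if slab.any() else 0.0
    model_mean = float(vm.mean())
    return StressRegionMetrics(
        peak_von_mises=peak,
        aspect_ratio=aspect,
        shielded=slab_mean < 0.25 * model_mean,
        slab_mean=slab_mean,
        model_mean=model_mean,
    )


def orthotropic_tendon(constants: OrthotropicConstants) -> OrthotropicConstants:
    """Alias making intent explicit: axis 3 of the homogenised constants is
    the fibril direction and maps onto the tendon z axis of the macro model."""
    return constants
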