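"""Idealised repeating unit cell of tendon microstructure.

The cell is a square prism of edge ``d + s`` (fibril diameter plus
surface-to-surface gap) containing one centred cylindrical fibril per tile,
meshed with a conforming all-hexahedral butterfly (O-grid) pattern: a square
core inside the fibril, fibril ring layers out to the circular interface,
and matrix ring layers from the interface to the cell boundary.  Midside
nodes of quadratic elements on the interface are snapped onto the circle, so
the realised fibril volume fraction tracks the analytic
``pi d^2 / (4 (d + s)^2)`` closely.

Coordinates are nondimensionalised by the cell edge (linear elasticity is
scale invariant); moduli stay in MPa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .mesh import Mesh, MeshError, extrude_quads, hex8_to_hex20

FIBRIL = "fibril"
MATRIX = "matrix"

SQUARE_PACKING_MAX = math.pi / 4.0


class GeometryError(ValueError):
    """Unmeshable unit-cell geometry."""


def packing_volume_fraction(d: float, s: float) -> float:
    """Fibril volume fraction of a square packing.

    Parameters: fibril diameter ``d`` and surface-to-surface gap ``s``
    (same length unit, conventionally nm).  Returns
    ``pi d^2 / (4 (d + s)^2)``.
    """
    if d <= 0 or s < 0:
        raise GeometryError(f"need d > 0 and s >= 0, got d={d}, s={s}")
    return math.pi * d * d / (4.0 * (d + s) ** 2)


def gap_for_fraction(d: float, Vf_target: float, rounded: bool = False) -> float:
    """Fibril gap that realises a target volume fraction at diameter ``d``.

    Inverts :func:`packing_volume_fraction`:
    ``s = d (sqrt(pi / (4 Vf)) - 1)``.  With ``rounded=True`` the result is
    rounded to the nearest whole length unit (nm in the reference geometry,
    where d = 100 nm and Vf = 0.6 give s = 14 nm).
    """
    if d <= 0:
        raise GeometryError(f"need d > 0, got {d}")
    if not (0.0 < Vf_target <= SQUARE_PACKING_MAX):
        raise GeometryError(
            f"target volume fraction must be in (0, pi/4], got {Vf_target}"
        )
    s = d * (math.sqrt(math.pi / (4.0 * Vf_target)) - 1.0)
    return float(round(s)) if rounded else s


@dataclass(frozen=True)
class UnitCellSpec:
    """Geometry, mesh density and phase properties of the unit cell.

    Reference geometry: fibril diameter 100 nm with a 14 nm gap
    (volume fraction 0.6043); fibril modulus 1,700 MPa, shared Poisson
    ratio 0.3.  ``fibril_count_per_edge`` tiles the single-fibril pattern
    into a larger cell to dilute boundary effects.
    """

    fibril_diameter: float = 100.0  # nm
    fibril_gap: float = 14.0  # nm
    fibril_count_per_edge: int = 1
    extrusion_length: float | None = None  # nm; default: one cell edge
    fibril_modulus: float = 1700.0  # MPa
    matrix_modulus: float = 1000.0  # MPa
    poisson_ratio: float = 0.3
    # mesh density controls
    core_divisions: int = 3  # core square is (2q)^2 quads
    fibril_layers: int = 2
    matrix_layers: int = 6
    axial_layers: int = 2

    @property
    def cell_edge(self) -> float:
        return self.fibril_diameter + self.fibril_gap

    @property
    def analytic_volume_fraction(self) -> float:
        return packing_volume_fraction(self.fibril_diameter, self.fibril_gap)

    def scaled_density(self, factor: float) -> "UnitCellSpec":
        """A spec with all mesh-density controls scaled by ``factor``."""
        return replace(
            self,
            core_divisions=max(1, round(self.core_divisions * factor)),
            fibril_layers=max(1, round(self.fibril_layers * factor)),
            matrix_layers=max(1, round(self.matrix_layers * factor)),
            axial_layers=max(1, round(self.axial_layers * factor)),
        )


def _butterfly_2d(spec: UnitCellSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Single-tile butterfly quad mesh on [-1/2, 1/2]^2 (cell-edge units).

    Returns (nodes2d, quads, is_fibril).
    """
    q = spec.core_divisions
    nf, nm = spec.fibril_layers, spec.matrix_layers
    r = 0.5 * spec.fibril_diameter / spec.cell_edge  # fibril radius, edge units
    H = 0.5
    if r >= H:
        raise GeometryError("fibril diameter exceeds cell edge (overlapping fibrils)")
    a = 0.5 * r  # core square half-width

    # core grid
    lin = np.linspace(-a, a, 2 * q + 1)
    core_nodes = np.array([(x, y) for y in lin for x in lin])

    def core_id(i: int, j: int) -> int:  # i: x index, j: y index
        return j * (2 * q + 1) + i

    quads: list[list[int]] = []
    is_fib: list[bool] = []
    for j in range(2 * q):
        for i in range(2 * q):
            quads.append([core_id(i, j), core_id(i + 1, j),
                          core_id(i + 1, j + 1), core_id(i, j + 1)])
            is_fib.append(True)

    # counter-clockwise core boundary node loop, starting at (-a, -a)
    loop: list[int] = []
    loop += [core_id(i, 0) for i in range(2 * q)]
    loop += [core_id(2 * q, j) for j in range(2 * q)]
    loop += [core_id(i, 2 * q) for i in range(2 * q, 0, -1)]
    loop += [core_id(0, j) for j in range(2 * q, 0, -1)]
    nray = len(loop)  # 8q rays

    nodes = [core_nodes]
    next_id = len(core_nodes)
    ring_ids = np.empty((nf + nm + 1, nray), dtype=np.int64)
    ring_ids[0] = loop
    new_pts: list[np.ndarray] = []
    for k, nid in enumerate(loop):
        p = core_nodes[nid]
        rho0 = float(np.hypot(*p))
        u = p / rho0
        r_out = H / np.max(np.abs(u))
        radii = np.concatenate([
            np.linspace(rho0, r, nf + 1)[1:],
            np.linspace(r, r_out, nm + 1)[1:],
        ])
        for layer, rho in enumerate(radii, start=1):
            ring_ids[layer, k] = next_id
            new_pts.append(rho * u)
            next_id += 1
    nodes.append(np.array(new_pts))

    for layer in range(1, nf + nm + 1):
        for k in range(nray):
            k1 = (k + 1) % nray
            quads.append([ring_ids[layer - 1, k], ring_ids[layer, k],
                          ring_ids[layer, k1], ring_ids[layer - 1, k1]])
            is_fib.append(layer <= nf)

    return np.vstack(nodes), np.array(quads, dtype=np.int64), np.array(is_fib)


def _dedup_nodes(nodes: np.ndarray, conn: np.ndarray, decimals: int = 9):
    """Merge coincident nodes (rounded-coordinate hashing)."""
    key = np.round(nodes, decimals)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return nodes[first], inverse[conn]


def build_unit_cell(spec: UnitCellSpec) -> Mesh:
    """Conforming quadratic hex mesh of the unit cell with phase labels.

    The mesh spans ``[0, k]^2 x [0, Lz]`` in cell-edge units, where ``k`` is
    ``fibril_count_per_edge``; fibril centres sit at (i + 1/2, j + 1/2).
    """
    if spec.fibril_diameter <= 0 or spec.fibril_gap < 0:
        raise GeometryError("need fibril_diameter > 0 and fibril_gap >= 0")
    k = spec.fibril_count_per_edge
    if k < 1:
        raise GeometryError("fibril_count_per_edge must be >= 1")

    tile_nodes, tile_quads, tile_fib = _butterfly_2d(spec)
    # tile the pattern: shift tile (centred on origin) to (i+1/2, j+1/2)
    all_nodes, all_quads, all_fib = [], [], []
    offset = 0
    for j in range(k):
        for i in range(k):
            all_nodes.append(tile_nodes + np.array([i + 0.5, j + 0.5]))
            all_quads.append(tile_quads + offset)
            all_fib.append(tile_fib)
            offset += len(tile_nodes)
    nodes2d = np.vstack(all_nodes)
    quads = np.vstack(all_quads)
    is_fib = np.concatenate(all_fib)
    nodes2d, quads = _dedup_nodes(nodes2d, quads)

    Lz_phys = spec.extrusion_length if spec.extrusion_length else spec.cell_edge
    Lz = Lz_phys / spec.cell_edge
    nodes8, conn8 = extrude_quads(nodes2d, quads, Lz, spec.axial_layers)
    labels8 = np.tile(np.where(is_fib, FIBRIL, MATRIX), spec.axial_layers)

    nodes20, conn20 = hex8_to_hex20(nodes8, conn8)
    _snap_interface_midnodes(nodes20, conn20, spec)
    mesh = Mesh(nodes20, conn20, labels8.astype(object))
    mesh.check_jacobians()

    vf = realised_volume_fraction(mesh)
    if abs(vf - spec.analytic_volume_fraction) > 5e-3:
        raise GeometryError(
            f"realised volume fraction {vf:.5f} deviates from analytic "
            f"{spec.analytic_volume_fraction:.5f} by more than 0.5% absolute"
        )
    return mesh


def _snap_interface_midnodes(nodes: np.ndarray, conn: np.ndarray, spec: UnitCellSpec) -> None:
    """Move midside nodes of fibril-interface edges onto the circular arcs."""
    r = 0.5 * spec.fibril_diameter / spec.cell_edge
    k = spec.fibril_count_per_edge
    centres = np.array([(i + 0.5, j + 0.5) for j in range(k) for i in range(k)])
    xy = nodes[:, :2]
    d2 = ((xy[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    ci = np.argmin(d2, axis=1)
    rad = np.sqrt(d2[np.arange(len(nodes)), ci])
    on_circle = np.abs(rad - r) < 1e-6

    from .elements import HEX20_EDGES

    for elem in conn:
        for eidx, (A, B) in enumerate(HEX20_EDGES):
            na, nb, nmid = elem[A], elem[B], elem[8 + eidx]
            if on_circle[na] and on_circle[nb] and ci[na] == ci[nb]:
                c = centres[ci[na]]
                v = nodes[nmid, :2] - c
                nv = np.linalg.norm(v)
                if nv > 0:
                    nodes[nmid, :2] = c + v * (r / nv)


def realised_volume_fraction(mesh: Mesh) -> float:
    """Fibril volume fraction of a generated mesh (quadrature volumes)."""
    vols = mesh.element_volumes()
    fib = np.asarray(mesh.material_labels) == FIBRIL
    return float(vols[fib].sum() / vols.sum())


def phase_materials(spec: UnitCellSpec):
    """Material map {fibril, matrix} for the spec's phase properties."""
    from .materials import IsotropicElastic

    return {
        FIBRIL: IsotropicElastic(spec.fibril_modulus, spec.poisson_ratio),
        MATRIX: IsotropicElastic(spec.matrix_modulus, spec.poisson_ratio),
    }
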