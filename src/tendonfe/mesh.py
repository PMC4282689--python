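"""Mesh container, structured hex meshing utilities, and mesh I/O.

The only element type supported is the 20-node serendipity hexahedron whose
node ordering is documented in :mod:`tendonfe.elements`.  Meshes are built
as 8-node grids and promoted to quadratic by inserting shared midside nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .elements import HEX20_EDGES, hex20_shape, integration_points


class MeshError(ValueError):
    """Invalid mesh geometry or topology."""


@dataclass
class Mesh:
    """Unstructured mesh of 20-node hexahedra.

    Attributes
    ----------
    nodes : (n_nodes, 3) float array
        Node coordinates in a consistent length unit.
    elements : (n_elements, 20) int array
        Connectivity, node ordering per :mod:`tendonfe.elements`.
    material_labels : (n_elements,) array of str
        Material identifier per element (e.g. ``"fibril"``/``"matrix"``).
    """

    nodes: np.ndarray
    elements: np.ndarray
    material_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != 20:
            raise MeshError("elements must be (n_elements, 20)")
        if self.elements.min(initial=0) < 0 or (
            self.elements.size and self.elements.max() >= len(self.nodes)
        ):
            raise MeshError("element connectivity references out-of-range nodes")
        if self.material_labels is None:
            self.material_labels = np.full(len(self.elements), "default", dtype=object)
        else:
            self.material_labels = np.asarray(self.material_labels, dtype=object)
            if len(self.material_labels) != len(self.elements):
                raise MeshError("one material label per element required")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self, e: int) -> np.ndarray:
        return self.nodes[self.elements[e]]

    def element_volumes(self, rule: str | int = "full") -> np.ndarray:
        """Per-element volume by Gauss quadrature of the Jacobian."""
        pts, wts = integration_points(rule)
        _, dN = hex20_shape(pts)  # (G,20,3)
        coords = self.nodes[self.elements]  # (E,20,3)
        J = np.einsum("gai,eaj->egij", dN, coords)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            bad = np.unique(np.where(detJ <= 0)[0])
            raise MeshError(f"non-positive Jacobian in elements {bad[:10].tolist()}")
        return detJ @ wts

    def volume(self) -> float:
        return float(self.element_volumes().sum())

    def check_jacobians(self, rule: str | int = "full") -> None:
        """Raise MeshError if any element has a non-positive Jacobian."""
        self.element_volumes(rule)

    def boundary_nodes(self, tol: float = 1e-9) -> np.ndarray:
        """Indices of nodes on the axis-aligned bounding box of the mesh.

        Valid for the block-shaped domains used in this package (unit cell,
        tendon quarter block).
        """
        lo = self.nodes.min(axis=0)
        hi = self.nodes.max(axis=0)
        span = max(hi.max() - lo.min(), 1.0)
        on = (np.abs(self.nodes - lo) < tol * span) | (np.abs(self.nodes - hi) < tol * span)
        return np.where(on.any(axis=1))[0]

    def nodes_on_plane(self, axis: int, value: float, tol: float = 1e-9) -> np.ndarray:
        span = max(np.ptp(self.nodes[:, axis]), 1.0)
        return np.where(np.abs(self.nodes[:, axis] - value) < tol * span)[0]

    def element_centroids(self) -> np.ndarray:
        # corner-node mean is adequate for binning/metrics
        return self.nodes[self.elements[:, :8]].mean(axis=1)


def hex8_to_hex20(nodes: np.ndarray, conn8: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Promote an 8-node hex mesh to 20 nodes with shared midside nodes.

    Midside nodes are placed at edge midpoints; callers may move them
    afterwards (e.g. snap onto a curved interface).
    """
    nodes = np.asarray(nodes, dtype=float)
    conn8 = np.asarray(conn8, dtype=np.int64)
    edge_mid: dict[tuple[int, int], int] = {}
    new_nodes = [nodes]
    next_id = len(nodes)
    conn20 = np.empty((len(conn8), 20), dtype=np.int64)
    conn20[:, :8] = conn8
    mids = []
    for e, elem in enumerate(conn8):
        for k, (a, b) in enumerate(HEX20_EDGES):
            key = (min(elem[a], elem[b]), max(elem[a], elem[b]))
            idx = edge_mid.get(key)
            if idx is None:
                idx = next_id
                edge_mid[key] = idx
                mids.append(0.5 * (nodes[elem[a]] + nodes[elem[b]]))
                next_id += 1
            conn20[e, 8 + k] = idx
    if mids:
        new_nodes.append(np.array(mids))
    return np.vstack(new_nodes), conn20


def box_mesh(
    lengths: tuple[float, float, float],
    divisions: tuple[int, int, int],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    label: str = "default",
) -> Mesh:
    """Structured 20-node hexahedral mesh of an axis-aligned box."""
    nx, ny, nz = divisions
    if min(nx, ny, nz) < 1:
        raise MeshError("divisions must be >= 1")
    xs = np.linspace(origin[0], origin[0] + lengths[0], nx + 1)
    ys = np.linspace(origin[1], origin[1] + lengths[1], ny + 1)
    zs = np.linspace(origin[2], origin[2] + lengths[2], nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    conn8 = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                conn8.append(
                    [
                        nid(i, j, k), nid(i + 1, j, k),
                        nid(i + 1, j + 1, k), nid(i, j + 1, k),
                        nid(i, j, k + 1), nid(i + 1, j, k + 1),
                        nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                    ]
                )
    nodes20, conn20 = hex8_to_hex20(nodes, np.array(conn8))
    return Mesh(nodes20, conn20, np.full(len(conn20), label, dtype=object))


def extrude_quads(
    nodes2d: np.ndarray,
    quads: np.ndarray,
    length: float,
    layers: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Extrude a quad mesh along z into an 8-node hex mesh.

    Quads must be counter-clockwise in the xy-plane so that hexes have
    positive Jacobians.
    """
    n2d = len(nodes2d)
    zs = np.linspace(0.0, length, layers + 1)
    nodes = np.vstack([
        np.column_stack([nodes2d, np.full(n2d, z)]) for z in zs
    ])
    conn = []
    for k in range(layers):
        lo, hi = k * n2d, (k + 1) * n2d
        for q in quads:
            conn.append([lo + q[0], lo + q[1], lo + q[2], lo + q[3],
                         hi + q[0], hi + q[1], hi + q[2], hi + q[3]])
    return nodes, np.array(conn, dtype=np.int64)


# ---------------------------------------------------------------------------
# I/O

VTK_QUADRATIC_HEX = 25

# VTK quadratic hexahedron uses the same node ordering as this package.


def write_vtk(
    path,
    mesh: Mesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "tendonfe output",
) -> None:
    """Write a legacy-ASCII VTK unstructured grid (quadratic hexahedra).

    Material labels are always emitted as an integer cell field
    ``material_id`` (with the label->id map in the header comment line).
    """
    labels = list(dict.fromkeys(mesh.material_labels.tolist()))
    label_ids = {lab: i for i, lab in enumerate(labels)}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{title} | material_id map: {label_ids}\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.12g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 21}\n")
        cells = np.column_stack([np.full(mesh.n_elements, 20), mesh.elements])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, VTK_QUADRATIC_HEX), fmt="%d")

        cd = {"material_id": np.array([label_ids[l] for l in mesh.material_labels])}
        if cell_data:
            cd.update(cell_data)
        f.write(f"CELL_DATA {mesh.n_elements}\n")
        for name, arr in cd.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
                f.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, arr.reshape(-1, 1), fmt="%.12g")
            else:
                f.write(f"FIELD {name}_field 1\n")
                f.write(f"{name} {arr.shape[1]} {arr.shape[0]} double\n")
                np.savetxt(f, arr, fmt="%.12g")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.12g")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr.reshape(-1, 1), fmt="%.12g")


INTERCHANGE_HEADER = (
    "# tendonfe plain-text mesh v1\n"
    "# node ordering: 8 corners then 12 midside nodes "
    "(bottom ring, top ring, verticals); see tendonfe.elements\n"
)


def write_mesh_text(path, mesh: Mesh) -> None:
    """Plain-text mesh interchange: node table + connectivity table."""
    with open(path, "w") as f:
        f.write(INTERCHANGE_HEADER)
        f.write(f"NODES {mesh.n_nodes}\n")
        np.savetxt(f, mesh.nodes, fmt="%.17g")
        f.write(f"ELEMENTS {mesh.n_elements}\n")
        for elem, lab in zip(mesh.elements, mesh.material_labels):
            f.write(" ".join(map(str, elem)) + f" {lab}\n")


def read_mesh_text(path) -> Mesh:
    with open(path) as f:
        lines = [ln for ln in f if not ln.startswith("#")]
    i = 0
    tag, n_nodes = lines[i].split()
    if tag != "NODES":
        raise MeshError("malformed mesh file: expected NODES header")
    n_nodes = int(n_nodes)
    nodes = np.loadtxt(lines[i + 1 : i + 1 + n_nodes], ndmin=2)
    i += 1 + n_nodes
    tag, n_el = lines[i].split()
    if tag != "ELEMENTS":
        raise MeshError("malformed mesh file: expected ELEMENTS header")
    n_el = int(n_el)
    conn = np.empty((n_el, 20), dtype=np.int64)
    labels = np.empty(n_el, dtype=object)
    for e in range(n_el):
        parts = lines[i + 1 + e].split()
        conn[e] = [int(p) for p in parts[:20]]
        labels[e] = parts[20] if len(parts) > 20 else "default"
    return Mesh(nodes, conn, labels)
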