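"""Serendipity 20-node hexahedral element: shape functions and quadrature.

Node ordering convention (fixed for the whole package; identical to the
VTK quadratic-hexahedron and Abaqus C3D20 orderings):

====  =================  ==========================================
node  reference coords   description
====  =================  ==========================================
0     (-1, -1, -1)       corner, bottom face (zeta = -1)
1     (+1, -1, -1)       corner
2     (+1, +1, -1)       corner
3     (-1, +1, -1)       corner
4     (-1, -1, +1)       corner, top face (zeta = +1)
5     (+1, -1, +1)       corner
6     (+1, +1, +1)       corner
7     (-1, +1, +1)       corner
8     ( 0, -1, -1)       mid-edge 0-1
9     (+1,  0, -1)       mid-edge 1-2
10    ( 0, +1, -1)       mid-edge 2-3
11    (-1,  0, -1)       mid-edge 3-0
12    ( 0, -1, +1)       mid-edge 4-5
13    (+1,  0, +1)       mid-edge 5-6
14    ( 0, +1, +1)       mid-edge 6-7
15    (-1,  0, +1)       mid-edge 7-4
16    (-1, -1,  0)       mid-edge 0-4 (vertical)
17    (+1, -1,  0)       mid-edge 1-5
18    (+1, +1,  0)       mid-edge 2-6
19    (-1, +1,  0)       mid-edge 3-7
====  =================  ==========================================
"""

from __future__ import annotations

import numpy as np

#: Reference coordinates of the 20 nodes, following the table above.
HEX20_REF_COORDS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
        [0, -1, -1], [1, 0, -1], [0, 1, -1], [-1, 0, -1],
        [0, -1, 1], [1, 0, 1], [0, 1, 1], [-1, 0, 1],
        [-1, -1, 0], [1, -1, 0], [1, 1, 0], [-1, 1, 0],
    ],
    dtype=float,
)

#: Node pairs defining the 12 edges of the underlying 8-node hexahedron,
#: in the order in which their midside nodes appear (nodes 8..19).
HEX20_EDGES = [
    (0, 1), (1, 2), (2, 3), (3, 0),
    (4, 5), (5, 6), (6, 7), (7, 4),
    (0, 4), (1, 5), (2, 6), (3, 7),
]


def hex20_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions and local gradients of the 20-node serendipity hex.

    Parameters
    ----------
    xi : array-like, shape (3,) or (npts, 3)
        Local coordinates in the reference cube [-1, 1]^3.

    Returns
    -------
    N : ndarray, shape (..., 20)
        Shape function values.
    dN : ndarray, shape (..., 20, 3)
        Gradients with respect to the local coordinates.
    """
    xi = np.asarray(xi, dtype=float)
    single = xi.ndim == 1
    pts = np.atleast_2d(xi)
    g, h, r = pts[:, 0], pts[:, 1], pts[:, 2]
    n = pts.shape[0]
    N = np.empty((n, 20))
    dN = np.empty((n, 20, 3))

    for a in range(20):
        ga, ha, ra = HEX20_REF_COORDS[a]
        if a < 8:  # corner
            f = (1 + g * ga) * (1 + h * ha) * (1 + r * ra)
            s = g * ga + h * ha + r * ra - 2.0
            N[:, a] = 0.125 * f * s
            dN[:, a, 0] = 0.125 * ga * (1 + h * ha) * (1 + r * ra) * (s + (1 + g * ga))
            dN[:, a, 1] = 0.125 * ha * (1 + g * ga) * (1 + r * ra) * (s + (1 + h * ha))
            dN[:, a, 2] = 0.125 * ra * (1 + g * ga) * (1 + h * ha) * (s + (1 + r * ra))
        elif ga == 0:  # midside on a xi-direction edge
            N[:, a] = 0.25 * (1 - g**2) * (1 + h * ha) * (1 + r * ra)
            dN[:, a, 0] = -0.5 * g * (1 + h * ha) * (1 + r * ra)
            dN[:, a, 1] = 0.25 * (1 - g**2) * ha * (1 + r * ra)
            dN[:, a, 2] = 0.25 * (1 - g**2) * (1 + h * ha) * ra
        elif ha == 0:
            N[:, a] = 0.25 * (1 - h**2) * (1 + g * ga) * (1 + r * ra)
            dN[:, a, 0] = 0.25 * (1 - h**2) * ga * (1 + r * ra)
            dN[:, a, 1] = -0.5 * h * (1 + g * ga) * (1 + r * ra)
            dN[:, a, 2] = 0.25 * (1 - h**2) * (1 + g * ga) * ra
        else:  # ra == 0
            N[:, a] = 0.25 * (1 - r**2) * (1 + g * ga) * (1 + h * ha)
            dN[:, a, 0] = 0.25 * (1 - r**2) * ga * (1 + h * ha)
            dN[:, a, 1] = 0.25 * (1 - r**2) * (1 + g * ga) * ha
            dN[:, a, 2] = -0.5 * r * (1 + g * ga) * (1 + h * ha)

    if single:
        return N[0], dN[0]
    return N, dN


def gauss_rule(npts_per_axis: int) -> tuple[np.ndarray, np.ndarray]:
    """Tensor-product Gauss-Legendre rule on [-1, 1]^3.

    Returns (points, weights) with points of shape (npts^3, 3).
    """
    x, w = np.polynomial.legendre.leggauss(npts_per_axis)
    pts = np.array([[a, b, c] for a in x for b in x for c in x])
    wts = np.array([wa * wb * wc for wa in w for wb in w for wc in w])
    return pts, wts


#: Named integration rules.  "reduced" is the 2x2x2 rule of the C3D20R
#: element; "full" is 3x3x3.
INTEGRATION_RULES = {"reduced": 2, "full": 3}


def integration_points(rule: str | int) -> tuple[np.ndarray, np.ndarray]:
    """Integration points/weights for a named rule ("reduced"/"full") or an int."""
    if isinstance(rule, str):
        try:
            n = INTEGRATION_RULES[rule]
        except KeyError:
            raise ValueError(f"unknown integration rule {rule!r}") from None
    else:
        n = int(rule)
    return gauss_rule(n)
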