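"""Linear-elastic material models and their 6x6 Voigt matrices.

Voigt ordering used throughout the package (engineering shear strains,
gamma_ij = 2 eps_ij):

    [s11, s22, s33, t12, t13, t23]   /   [e11, e22, e33, g12, g13, g23]

For the tendon microstructure, direction 3 is the fibril (tendon) axis and
directions 1-2 span the transverse plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VOIGT_COMPONENTS = ("11", "22", "33", "12", "13", "23")


class MaterialError(ValueError):
    """Invalid material parameters."""


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic linear-elastic solid.

    Parameters
    ----------
    young_modulus : float
        Young's modulus, MPa.
    poisson_ratio : float
        Poisson's ratio, must lie in (-1, 0.5).
    """

    young_modulus: float
    poisson_ratio: float

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise MaterialError(f"young_modulus must be > 0, got {self.young_modulus}")
        if not (-1.0 < self.poisson_ratio < 0.5):
            raise MaterialError(
                f"poisson_ratio must be in (-1, 0.5), got {self.poisson_ratio}"
            )

    @property
    def shear_modulus(self) -> float:
        return self.young_modulus / (2.0 * (1.0 + self.poisson_ratio))

    def stiffness_matrix(self) -> np.ndarray:
        """6x6 stiffness in Voigt/engineering-shear convention."""
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = self.shear_modulus
        D = np.zeros((6, 6))
        D[:3, :3] = lam
        D[np.diag_indices(3)] = lam + 2 * mu
        D[3, 3] = D[4, 4] = D[5, 5] = mu
        return D


@dataclass(frozen=True)
class OrthotropicConstants:
    """The nine engineering constants of an orthotropic solid.

    Direction 3 is the fibril / tendon axis.  The reciprocal relation
    nu_ij / E_i = nu_ji / E_j is enforced by construction: only nu12, nu13,
    nu23 are stored and the conjugate ratios are derived.
    """

    E1: float
    E2: float
    E3: float
    nu12: float
    nu13: float
    nu23: float
    G12: float
    G13: float
    G23: float

    def __post_init__(self) -> None:
        for name in ("E1", "E2", "E3", "G12", "G13", "G23"):
            if getattr(self, name) <= 0:
                raise MaterialError(f"{name} must be > 0")
        S = self.compliance_matrix()
        try:
            np.linalg.cholesky(S)
        except np.linalg.LinAlgError:
            raise MaterialError(
                "engineering constants do not define a positive-definite compliance"
            ) from None

    def compliance_matrix(self) -> np.ndarray:
        """6x6 compliance in Voigt/engineering-shear convention (symmetric)."""
        S = np.zeros((6, 6))
        E1, E2, E3 = self.E1, self.E2, self.E3
        S[0, 0], S[1, 1], S[2, 2] = 1 / E1, 1 / E2, 1 / E3
        S[0, 1] = S[1, 0] = -self.nu12 / E1
        S[0, 2] = S[2, 0] = -self.nu13 / E1
        S[1, 2] = S[2, 1] = -self.nu23 / E2
        S[3, 3] = 1 / self.G12
        S[4, 4] = 1 / self.G13
        S[5, 5] = 1 / self.G23
        return S

    def stiffness_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.compliance_matrix())

    @classmethod
    def from_compliance(cls, S: np.ndarray) -> "OrthotropicConstants":
        """Engineering constants from an orthotropic 6x6 compliance matrix."""
        S = np.asarray(S, dtype=float)
        E = 1.0 / np.diag(S)[:3]
        return cls(
            E1=E[0], E2=E[1], E3=E[2],
            nu12=-S[1, 0] * E[0],
            nu13=-S[2, 0] * E[0],
            nu23=-S[2, 1] * E[1],
            G12=1.0 / S[3, 3],
            G13=1.0 / S[4, 4],
            G23=1.0 / S[5, 5],
        )

    @classmethod
    def isotropic(cls, E: float, nu: float) -> "OrthotropicConstants":
        G = E / (2 * (1 + nu))
        return cls(E, E, E, nu, nu, nu, G, G, G)

    def as_tuple(self) -> tuple[float, ...]:
        return (self.E1, self.E2, self.E3, self.nu12, self.nu13, self.nu23,
                self.G12, self.G13, self.G23)


Material = IsotropicElastic | OrthotropicConstants


def stiffness_of(material: Material) -> np.ndarray:
    """6x6 Voigt stiffness of either material type."""
    return material.stiffness_matrix()
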