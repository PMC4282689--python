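"""Synthetic laboratory data with the statistical structure of the ex vivo
tests that inform the model.

Two experiment families are emulated:

* transverse tensile tests on rectangular tendon samples (nominally 5 mm
  wide, 2 mm thick, 2.5 mm grip gauge, n = 12 per group): a low-stiffness
  toe region blending into a linear region whose slope is the transverse
  modulus, followed by a departure from linearity at a peak stress;
* half-Kessler repair load-displacement tests, recorded through a testing
  machine whose frame compliance must be subtracted, after a 0.1 N
  pretension take-up.

The reference group means are 0.2551 MPa (proximal) and 0.1035 MPa (distal)
for the transverse modulus; the measured curves stop behaving linearly near
0.16 / 0.10 MPa.  The generators are seed-deterministic and emit their spec
alongside the data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, asdict, replace

import numpy as np

#: Group means of the transverse linear modulus, MPa.
PROXIMAL_MODULUS = 0.2551
DISTAL_MODULUS = 0.1035
#: Stress at which the measured mean curves depart from linearity, MPa.
PROXIMAL_LINEAR_LIMIT = 0.16
DISTAL_LINEAR_LIMIT = 0.10


class CurveInputError(ValueError):
    """Degenerate or inconsistent curve data."""


@dataclass(frozen=True)
class TransverseTestSpec:
    """Generator settings for one transverse tensile sample group.

    ``noise_sd`` is additive Gaussian stress noise (MPa);
    ``modulus_cv`` is the between-sample coefficient of variation of the
    true modulus (biological scatter); dimension jitter emulates calliper
    uncertainty on the nominal 5 x 2 mm cross-section and the 2.5 mm gauge.
    Strain rate (1-10 %/s) only labels the sample: transversely the modulus
    is rate independent over that range.
    """

    true_linear_modulus: float = PROXIMAL_MODULUS  # MPa
    toe_strain_extent: float = 0.05
    failure_stress: float = PROXIMAL_LINEAR_LIMIT  # MPa, end of linearity
    strain_rate: float = 1.0  # %/s, in [1, 10]
    noise_sd: float = 0.002  # MPa
    modulus_cv: float = 0.25  # between-sample scatter
    width: float = 5.0  # mm
    thickness: float = 2.0  # mm
    gauge_length: float = 2.5  # mm
    dimension_jitter_cv: float = 0.02
    n_samples: int = 12
    n_points: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_linear_modulus <= 0 or self.failure_stress <= 0:
            raise CurveInputError("modulus and failure stress must be positive")
        if not (0 <= self.toe_strain_extent < self.failure_strain):
            raise CurveInputError("toe region must end before failure")
        if not (1.0 <= self.strain_rate <= 10.0):
            raise CurveInputError("strain rate outside the tested 1-10 %/s range")

    @property
    def toe_stress(self) -> float:
        # C1 cubic toe carries half the linear-trend stress at its end
        return 0.5 * self.true_linear_modulus * self.toe_strain_extent

    @property
    def failure_strain(self) -> float:
        toe_sigma = 0.5 * self.true_linear_modulus * self.toe_strain_extent
        return self.toe_strain_extent + (self.failure_stress - toe_sigma) / self.true_linear_modulus


@dataclass
class StressStrainCurve:
    """Ordered (strain, stress MPa) samples with generating metadata."""

    strain: np.ndarray
    stress: np.ndarray
    sample_id: str = ""
    spec: TransverseTestSpec | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.ndim != 1 or self.strain.shape != self.stress.shape:
            raise CurveInputError("strain and stress must be equal-length 1D arrays")
        if np.any(np.diff(self.strain) <= 0):
            raise CurveInputError("strain must be strictly increasing")

    def to_csv(self) -> str:
        buf = io.StringIO()
        if self.spec is not None:
            for k, v in asdict(self.spec).items():
                buf.write(f"# {k} = {v}\n")
        buf.write(f"# sample_id = {self.sample_id}\n")
        buf.write("strain,stress_MPa\n")
        for e, s in zip(self.strain, self.stress):
            buf.write(f"{e:.8g},{s:.8g}\n")
        return buf.getvalue()


def toe_linear_stress(spec: TransverseTestSpec, strain: np.ndarray, modulus: float | None = None) -> np.ndarray:
    """Noise-free toe + linear stress response.

    The toe is the unique cubic with zero stress and slope at the origin
    that meets the linear trend with C1 continuity at ``toe_strain_extent``;
    beyond the linear limit the response rolls off quadratically, producing
    a detectable departure from linearity near ``failure_stress``.
    """
    E = spec.true_linear_modulus if modulus is None else modulus
    et = spec.toe_strain_extent
    strain = np.asarray(strain, dtype=float)
    if et > 0:
        st = 0.5 * E * et  # toe-end stress of the C1 cubic
        t = np.clip(strain / et, 0.0, 1.0)
        # cubic p(t) on [0,1]: p(0)=p'(0)=0, p(1)=st, p'(1)=E*et
        a3 = E * et - 2 * st
        a2 = 3 * st - E * et
        toe = a2 * t**2 + a3 * t**3
    else:
        st = 0.0
        toe = np.zeros_like(strain)
    lin = st + E * (strain - et)
    sigma = np.where(strain < et, toe, lin)
    # departure from linearity: beyond the linear-limit strain the tangent
    # slope decays linearly to zero over a 15% strain margin (parabolic cap)
    e_fail = et + (spec.failure_stress - st) / E
    d_max = 0.15 * e_fail
    beyond = strain > e_fail
    if np.any(beyond):
        over = np.minimum(strain[beyond] - e_fail, d_max)
        sigma = sigma.copy()
        sigma[beyond] = spec.failure_stress + E * over * (1.0 - over / (2.0 * d_max))
    return sigma


def generate_transverse_curve(spec: TransverseTestSpec, sample_index: int = 0) -> StressStrainCurve:
    """One synthetic stress-strain curve; deterministic for a fixed seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, sample_index]))
    E = spec.true_linear_modulus
    if spec.modulus_cv > 0:
        E = E * float(np.exp(rng.normal(0.0, spec.modulus_cv)
                             - 0.5 * spec.modulus_cv**2))
    # dimension jitter: measured vs true cross-section differ slightly, so
    # the reduced stress (force / measured area) rescales the curve
    area_ratio = 1.0
    if spec.dimension_jitter_cv > 0:
        true_w = spec.width * (1 + rng.normal(0, spec.dimension_jitter_cv))
        true_t = spec.thickness * (1 + rng.normal(0, spec.dimension_jitter_cv))
        area_ratio = (true_w * true_t) / (spec.width * spec.thickness)
    strain_max = 1.15 * spec.failure_strain
    strain = np.linspace(0.0, strain_max, spec.n_points + 1)[1:]
    stress = toe_linear_stress(spec, strain, modulus=E) * area_ratio
    if spec.noise_sd > 0:
        stress = stress + rng.normal(0.0, spec.noise_sd, size=stress.shape)
    stress = np.clip(stress, 0.0, None)
    return StressStrainCurve(
        strain=strain, stress=stress,
        sample_id=f"seed{spec.seed}-s{sample_index}", spec=spec,
    )


def generate_transverse_group(spec: TransverseTestSpec) -> list[StressStrainCurve]:
    """The full sample group (default n = 12)."""
    return [generate_transverse_curve(spec, i) for i in range(spec.n_samples)]


def fit_linear_modulus(
    curve: StressStrainCurve,
    min_window_fraction: float = 0.3,
    n_starts: int = 25,
) -> float:
    """Slope of the most-linear window of the pre-failure curve.

    Sliding windows covering at least ``min_window_fraction`` of the strain
    range below the departure-from-linearity point are scored by their
    coefficient of determination; the best window's least-squares slope is
    returned (MPa).
    """
    if len(curve.strain) < 20:
        raise CurveInputError("need at least 20 points to fit a modulus")
    strain, stress = curve.strain, curve.stress
    # restrict to the pre-failure range: drop the trailing roll-off where the
    # curve visibly departs from its final linear trend
    limit = detect_linear_limit_index(curve)
    strain, stress = strain[:limit], stress[:limit]
    n = len(strain)
    wmin = max(10, int(min_window_fraction * n))
    best = (-np.inf, 0.0)
    for w in (wmin, int(1.4 * wmin), int(1.8 * wmin)):
        if w > n:
            continue
        starts = np.unique(np.linspace(0, n - w, n_starts).astype(int))
        for s in starts:
            x = strain[s : s + w]
            y = stress[s : s + w]
            slope, intercept = np.polyfit(x, y, 1)
            resid = y - (slope * x + intercept)
            ss_tot = np.sum((y - y.mean()) ** 2)
            if ss_tot <= 0:
                r2 = 1.0 if np.allclose(resid, 0) else -np.inf
            else:
                r2 = 1.0 - np.sum(resid**2) / ss_tot
            if r2 > best[0]:
                best = (r2, slope)
    return float(best[1])


def detect_linear_limit_index(curve: StressStrainCurve, tol: float = 0.05) -> int:
    """Index at which the curve departs from its upper linear trend.

    Fits the mid-range (40-80% of strain) with a line and walks forward to
    the first point whose shortfall from the extrapolated line exceeds
    ``tol`` x the line value.  Returns len(curve) if no departure is found.
    """
    strain, stress = curve.strain, curve.stress
    n = len(strain)
    lo, hi = int(0.4 * n), int(0.8 * n)
    slope, intercept = np.polyfit(strain[lo:hi], stress[lo:hi], 1)
    pred = slope * strain + intercept
    short = pred - stress
    thresh = tol * np.maximum(pred, 1e-12)
    beyond = np.where((short > thresh) & (np.arange(n) > hi))[0]
    return int(beyond[0]) if len(beyond) else n


def detect_linear_limit_stress(curve: StressStrainCurve) -> float:
    """Stress (MPa) at the departure-from-linearity point (inf if absent)."""
    i = detect_linear_limit_index(curve)
    if i >= len(curve.strain):
        return float("inf")
    return float(curve.stress[i])


# ---------------------------------------------------------------------------
# half-Kessler load-displacement emulation


@dataclass(frozen=True)
class KesslerTestSpec:
    """Half-Kessler tensile test emulation: linear repair + machine frame."""

    repair_stiffness: float = 2.5  # N/mm (suture-repair slope)
    toe_displacement: float = 0.3  # mm of low-stiffness take-up
    max_force: float = 3.0  # N
    machine_compliance: float = 0.05  # mm/N
    pretension: float = 0.1  # N, removed as a displacement offset
    noise_sd: float = 0.0  # N
    n_points: int = 150
    seed: int = 0


@dataclass
class ForceDisplacementCurve:
    """Ordered (displacement mm, force N) samples."""

    displacement: np.ndarray
    force: np.ndarray

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.displacement.shape != self.force.shape:
            raise CurveInputError("displacement and force must match in length")

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("displacement_mm,force_N\n")
        for d, f in zip(self.displacement, self.force):
            buf.write(f"{d:.8g},{f:.8g}\n")
        return buf.getvalue()


def repair_only_displacement(spec: KesslerTestSpec, force: np.ndarray) -> np.ndarray:
    """Displacement of the repair itself (toe take-up + linear stretch)."""
    f = np.asarray(force, dtype=float)
    toe_force = 0.25 * spec.max_force
    take_up = spec.toe_displacement * (1.0 - np.exp(-3.0 * f / toe_force))
    return take_up + f / spec.repair_stiffness


def generate_kessler_curve(spec: KesslerTestSpec) -> ForceDisplacementCurve:
    """Raw measured curve: repair + machine stretch, pretension offset removed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 77]))
    force = np.linspace(spec.pretension, spec.max_force, spec.n_points)
    disp = repair_only_displacement(spec, force) + spec.machine_compliance * force
    # displacements are recorded from the pretensioned state
    disp = disp - disp[0]
    force = force - spec.pretension
    if spec.noise_sd > 0:
        force = force + rng.normal(0, spec.noise_sd, force.shape)
    return ForceDisplacementCurve(disp, force)


def compliance_correct(
    raw_curve: ForceDisplacementCurve, machine_compliance: float
) -> ForceDisplacementCurve:
    """Subtract the machine-frame stretch: d_corr = d_meas - c * F."""
    if machine_compliance < 0:
        raise CurveInputError("machine compliance must be >= 0")
    return ForceDisplacementCurve(
        raw_curve.displacement - machine_compliance * raw_curve.force,
        raw_curve.force.copy(),
    )


def proximal_spec(seed: int = 0, **overrides) -> TransverseTestSpec:
    """Reference proximal-group generator settings."""
    return replace(
        TransverseTestSpec(
            true_linear_modulus=PROXIMAL_MODULUS,
            failure_stress=PROXIMAL_LINEAR_LIMIT,
            seed=seed,
        ),
        **overrides,
    )


def distal_spec(seed: int = 0, **overrides) -> TransverseTestSpec:
    """Reference distal-group generator settings."""
    return replace(
        TransverseTestSpec(
            true_linear_modulus=DISTAL_MODULUS,
            failure_stress=DISTAL_LINEAR_LIMIT,
            seed=seed,
        ),
        **overrides,
    )
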