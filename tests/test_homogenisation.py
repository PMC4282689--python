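"""Homogenisation pipeline: validation case, average-strain theorem,
bounds, transverse isotropy, and the constants extraction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tendonfe.fem import FEMInputError
from tendonfe.homogenisation import (
    CASE_LABELS,
    MacroStrainCase,
    effective_stiffness,
    engineering_constants,
    kubc_boundary,
    periodic_node_pairs,
    voigt_reuss_bounds,
)
from tendonfe.materials import IsotropicElastic
from tendonfe.mesh import box_mesh
from tendonfe.unit_cell import UnitCellSpec, build_unit_cell


class TestMacroStrainCase:
    def test_tension_case_prescribes_affine_displacement(self):
        mesh = box_mesh((1, 1, 2), (1, 1, 2))
        case = MacroStrainCase("tension-33", 1e-3)
        bcs = kubc_boundary(mesh, case)
        presc = {(n, a): v for n, a, v in bcs.displacements}
        top = mesh.nodes_on_plane(2, 2.0)[0]
        assert presc[(int(top), 2)] == pytest.approx(2e-3)
        assert presc[(int(top), 0)] == 0.0

    def test_shear_case_is_symmetric_tensor(self):
        case = MacroStrainCase("shear-12", 1e-3)
        eps = case.strain_tensor()
        assert eps[0, 1] == eps[1, 0] == pytest.approx(5e-4)
        assert np.allclose(eps, eps.T)
        assert case.voigt_vector()[3] == pytest.approx(1e-3)

    def test_magnitude_outside_small_strain_rejected(self):
        with pytest.raises(FEMInputError):
            MacroStrainCase("tension-11", 0.5)
        with pytest.raises(FEMInputError):
            MacroStrainCase("twist-11", 1e-3)


class TestEngineeringConstants:
    def test_isotropic_round_trip(self):
        D = IsotropicElastic(1700.0, 0.3).stiffness_matrix()
        constants, raw, asym = engineering_constants(D)
        expect = (1700.0, 1700.0, 1700.0, 0.3, 0.3, 0.3,
                  653.8461538, 653.8461538, 653.8461538)
        assert np.allclose(constants.as_tuple(), expect, rtol=1e-9)
        assert asym < 1e-12

    def test_diagonal_stiffness_gives_zero_poisson(self):
        constants, _, _ = engineering_constants(np.eye(6) * 100.0)
        assert constants.nu12 == pytest.approx(0.0, abs=1e-14)
        assert constants.E1 == constants.E2 == constants.E3 == pytest.approx(100.0)

    def test_compliance_reciprocity_holds(self, validation_homogenisation):
        c = validation_homogenisation.constants
        S = c.compliance_matrix()
        assert abs(S[0, 1] - S[1, 0]) < 1e-10

    def test_indefinite_input_rejected(self):
        with pytest.raises(FEMInputError):
            engineering_constants(-np.eye(6))


class TestValidationCase:
    """Equal phase moduli must homogenise back to the phase material."""

    def test_moduli_recovered(self, validation_homogenisation):
        c = validation_homogenisation.constants
        for E in (c.E1, c.E2, c.E3):
            assert abs(E - 1700.0) / 1700.0 < 5e-4
        for G in (c.G12, c.G13, c.G23):
            assert abs(G - 653.8461470) / 653.8461470 < 5e-4
        for nu in (c.nu12, c.nu13, c.nu23):
            assert abs(nu - 0.3) < 1e-6

    def test_average_strain_theorem(self, validation_homogenisation):
        for label, e_bar in validation_homogenisation.case_avg_strain.items():
            target = MacroStrainCase(label, 1e-3).voigt_vector()
            assert np.abs(e_bar - target).max() < 1e-8

    def test_report_carries_ten_significant_figures(self, validation_homogenisation):
        report = validation_homogenisation.report()
        assert "653.8461538" in report


class TestHomogenisationProperties:
    @settings(max_examples=4, derandomize=True, deadline=None)
    @given(st.floats(1.0, 3000.0), st.floats(0.05, 0.45))
    def test_homogeneous_recovery_is_exact(self, E, nu):
        """A one-phase cell recovers (E, nu) for arbitrary isotropic input."""
        spec = UnitCellSpec(
            fibril_modulus=E, matrix_modulus=E, poisson_ratio=nu,
            core_divisions=2, fibril_layers=1, matrix_layers=2, axial_layers=1,
        )
        res = effective_stiffness(spec, cases="transverse_isotropic")
        c = res.constants
        assert abs(c.E3 - E) / E < 1e-6
        assert abs(c.nu12 - nu) < 1e-6
        assert abs(c.G12 - E / (2 * (1 + nu))) / E < 1e-6

    def test_magnitude_invariance(self):
        spec = UnitCellSpec(matrix_modulus=500.0, core_divisions=2,
                            fibril_layers=1, matrix_layers=2, axial_layers=1)
        mesh = build_unit_cell(spec)
        r1 = effective_stiffness(spec, magnitude=1e-3, mesh=mesh)
        r2 = effective_stiffness(spec, magnitude=5e-3, mesh=mesh)
        assert np.allclose(r1.stiffness, r2.stiffness, rtol=1e-9)

    def test_transverse_isotropy_shortcut_matches_full_run(self):
        spec = UnitCellSpec(matrix_modulus=100.0, core_divisions=2,
                            fibril_layers=1, matrix_layers=2, axial_layers=1)
        mesh = build_unit_cell(spec)
        full = effective_stiffness(spec, cases="all", mesh=mesh)
        short = effective_stiffness(spec, cases="transverse_isotropic", mesh=mesh)
        assert np.allclose(full.stiffness, short.stiffness, rtol=1e-6, atol=1e-9)

    def test_kubc_stiffer_than_periodic(self):
        """Affine boundary conditions overconstrain the fluctuation field,
        so every KUBC diagonal stiffness bounds the periodic one."""
        spec = UnitCellSpec(matrix_modulus=10.0, core_divisions=2,
                            fibril_layers=1, matrix_layers=2, axial_layers=1)
        mesh = build_unit_cell(spec)
        kubc = effective_stiffness(spec, mesh=mesh, bc_type="kubc")
        pbc = effective_stiffness(spec, mesh=mesh, bc_type="periodic")
        assert np.all(np.diag(kubc.stiffness) >= np.diag(pbc.stiffness) - 1e-9)

    def test_periodic_pairs_cover_opposite_faces(self):
        mesh = build_unit_cell(UnitCellSpec(core_divisions=2, fibril_layers=1,
                                            matrix_layers=2, axial_layers=1))
        slaves, masters, shifts = periodic_node_pairs(mesh)
        assert len(slaves) > 0
        assert np.allclose(
            mesh.nodes[slaves] - shifts, mesh.nodes[masters], atol=1e-9
        )


class TestMatrixModulusLadder:
    """Behaviour across Em = 1000 -> 1 MPa (periodic homogenisation)."""

    def test_axial_modulus_within_voigt_reuss_bounds(self, periodic_sweep):
        for Em, res in periodic_sweep.items():
            lo, hi = voigt_reuss_bounds(1700.0, Em, res.realised_vf)
            assert lo * (1 - 1e-6) <= res.constants.E3 <= hi * (1 + 1e-6)

    def test_transverse_isotropy_before_symmetrisation(self, periodic_sweep):
        for res in periodic_sweep.values():
            assert res.asymmetry < 0.01

    def test_constants_decrease_with_matrix_modulus(self, periodic_sweep):
        ladder = [periodic_sweep[Em].constants.as_tuple()
                  for Em in (1000.0, 100.0, 10.0, 1.0)]
        arr = np.array(ladder)
        assert np.all(np.diff(arr, axis=0) <= 1e-9)

    def test_strong_anisotropy_at_low_matrix_modulus(self, periodic_sweep):
        c = periodic_sweep[10.0].constants
        assert c.nu13 < 0.05
        assert c.E1 / c.E3 < 0.06

    def test_refinement_changes_constants_below_two_percent(self):
        spec = UnitCellSpec(matrix_modulus=100.0)
        coarse = effective_stiffness(spec, bc_type="periodic").constants
        fine = effective_stiffness(
            spec.scaled_density(1.5), bc_type="periodic"
        ).constants
        a, b = np.array(coarse.as_tuple()), np.array(fine.as_tuple())
        assert np.max(np.abs(b - a) / np.abs(a)) < 0.02
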