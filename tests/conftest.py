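"""Shared fixtures: expensive FE solutions are session-scoped so the
unit-cell sweeps and macro-model solves are computed once."""

from __future__ import annotations

import numpy as np
import pytest

from tendonfe.homogenisation import effective_stiffness
from tendonfe.kessler import (
    KesslerSpec,
    LoadProgram,
    build_kessler_model,
    run_load_program,
)
from tendonfe.unit_cell import UnitCellSpec

MATRIX_MODULI = (1000.0, 100.0, 10.0, 1.0)


@pytest.fixture(scope="session")
def validation_homogenisation():
    """Equal-phase (Ef = Em = 1700 MPa, nu = 0.3) KUBC homogenisation."""
    return effective_stiffness(UnitCellSpec(matrix_modulus=1700.0))


@pytest.fixture(scope="session")
def periodic_sweep():
    """Periodic-BC homogenisation across the matrix-modulus ladder."""
    return {
        Em: effective_stiffness(
            UnitCellSpec(matrix_modulus=Em), bc_type="periodic"
        )
        for Em in MATRIX_MODULI
    }


@pytest.fixture(scope="session")
def kessler_isotropic():
    """Default isotropic (E = 200 MPa) quarter model at the 0.5 mm gap."""
    spec = KesslerSpec()
    model = build_kessler_model(spec)
    result = run_load_program(model, LoadProgram("gap", (0.5,)))
    return spec, model, result


@pytest.fixture(scope="session")
def kessler_orthotropic_sweep(periodic_sweep):
    """Orthotropic quarter models (one per matrix modulus) at the 0.5 mm gap."""
    out = {}
    for Em in MATRIX_MODULI:
        spec = KesslerSpec(tendon_material=periodic_sweep[Em].constants)
        model = build_kessler_model(spec)
        out[Em] = (spec, model, run_load_program(model, LoadProgram("gap", (0.5,))))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
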