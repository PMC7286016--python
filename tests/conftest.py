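"""Shared fixtures: phantom cases, beamlet matrices, and constructed
micro-instances for oracle checks."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import sparse

from autoplan import (
    Beam,
    Case,
    CostFunction,
    PrescriptionItem,
    Structure,
    Template,
    build_beamlet_matrix,
    make_hn_case,
    make_prostate_case,
)
from autoplan.dose import BeamletIndex, BeamletMatrix


@pytest.fixture(scope="session")
def prostate_case() -> Case:
    return make_prostate_case(seed=1, overlap_fraction=0.1)


@pytest.fixture(scope="session")
def prostate_matrix(prostate_case):
    return build_beamlet_matrix(prostate_case)


@pytest.fixture(scope="session")
def hn_case() -> Case:
    return make_hn_case(seed=1, n_dose_levels=2)


@pytest.fixture(scope="session")
def hn_matrix(hn_case):
    return build_beamlet_matrix(hn_case)


@pytest.fixture(scope="session")
def box_case() -> Case:
    """Small homogeneous square body with a central target, one beam."""
    body = np.zeros((20, 20), bool)
    body[2:18, 2:18] = True
    tgt = np.zeros((20, 20), bool)
    tgt[8:12, 8:12] = True
    return Case(
        grid_shape=(20, 20),
        voxel_size_mm=(4.0, 4.0),
        structures=[
            Structure("body", body, "body"),
            Structure("target", tgt, "target", prescribed_dose=60.0),
        ],
        beams=[Beam(0.0, 4.0)],
        seed=0,
    )


@pytest.fixture(scope="session")
def symmetric_case() -> Case:
    """Mirror-symmetric phantom: central target, two lateral OARs, two
    opposed lateral beams, so every path to the target crosses an OAR."""
    yy, xx = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
    body = ((yy - 11.5) ** 2 / 100 + (xx - 11.5) ** 2 / 121) <= 1
    tgt = (((yy - 11.5) ** 2 + (xx - 11.5) ** 2) <= 12) & body
    o_left = (((yy - 11.5) ** 2 + (xx - 4.5) ** 2) <= 5) & body & ~tgt
    o_right = (((yy - 11.5) ** 2 + (xx - 18.5) ** 2) <= 5) & body & ~tgt
    return Case(
        grid_shape=(24, 24),
        voxel_size_mm=(4.0, 4.0),
        structures=[
            Structure("body", body, "body"),
            Structure("target", tgt, "target", prescribed_dose=60.0),
            Structure("oar_left", o_left, "oar"),
            Structure("oar_right", o_right, "oar"),
        ],
        beams=[Beam(90.0, 4.0), Beam(270.0, 4.0)],
        seed=0,
    )


def make_micro_instance(seed: int):
    """A 3-beamlet, 12-voxel instance with a hand-built deposition matrix,
    small enough for exhaustive grid search over the weights.

    Returns (case, matrix, template, dense A)."""
    rng = np.random.default_rng(seed)
    n_beamlets, grid = 3, (3, 4)
    A = rng.uniform(0.0, 3.0, size=(12, n_beamlets)) * (rng.random((12, n_beamlets)) < 0.8)
    body = np.ones(grid, bool)
    tmask = np.zeros(grid, bool)
    tmask.ravel()[:5] = True
    omask = np.zeros(grid, bool)
    omask.ravel()[7:] = True
    case = Case(
        grid_shape=grid,
        voxel_size_mm=(4.0, 4.0),
        structures=[
            Structure("body", body, "body"),
            Structure("target", tmask, "target", prescribed_dose=50.0),
            Structure("oar", omask, "oar"),
        ],
        beams=[Beam(0.0, 4.0)],
        seed=seed,
    )
    matrix = BeamletMatrix(
        matrix=sparse.csr_matrix(A),
        index=[BeamletIndex(0, 0.0, float(i)) for i in range(n_beamlets)],
        grid_shape=grid,
        case_hash=case.case_hash(),
        mu_per_cm=0.05,
        sigma_mm=3.0,
    )
    template = Template(
        case_ref=case.case_hash(),
        cost_functions=[
            CostFunction(
                id="obj", structure="target", kind="quadratic_underdose",
                reference_dose=50.0, isoconstraint=0.0, role="objective",
            ),
            CostFunction(
                id="oar_rms", structure="oar", kind="quadratic_overdose",
                reference_dose=20.0, isoconstraint=3.0,
            ),
            CostFunction(
                id="cap", structure="body", kind="max_dose",
                reference_dose=60.0, isoconstraint=60.0,
            ),
        ],
        prescription_items=[
            PrescriptionItem.make("cov", "target", "V_D_at_least", 50.0, 95.0)
        ],
    )
    return case, matrix, template, A


@pytest.fixture()
def micro_instance():
    return make_micro_instance(0)
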