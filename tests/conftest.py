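"""Shared fixtures: small FE solves reused across test modules.

The pipeline cases here run at deliberately coarse desk-scale resolutions so
the whole suite stays fast; the acceptance tests compare against printed
reference values with tolerances that account for this.
"""

from __future__ import annotations

import numpy as np
import pytest

import aawall as aw
from aawall.study import StudyRunner


TEST_RESOLUTION = (32, 18, 2)     # (nz, ntheta, nr) cells for AAA/referent cases
TEST_INCREMENTS = 4


@pytest.fixture(scope="session")
def runner():
    """Coarse, cached study runner shared by the acceptance-level tests."""
    return StudyRunner(
        target_edge=3.2,
        bc=aw.BoundaryConditions(pressure=0.016, increments=TEST_INCREMENTS),
        settings=aw.SolverSettings(),
        resolution=TEST_RESOLUTION,
        keep_fields=True,
    )


@pytest.fixture(scope="session")
def tube_case():
    """Plane-strain (axial roller) thick-walled cylinder solve + oracle."""
    mat = aw.REFERENT_NORMAL
    tube = aw.build_cylinder(8.0, 10.0, 30.0)
    mesh = aw.generate_mesh(tube, 2.6, resolution=(12, 30, 2))
    bc = aw.BoundaryConditions(pressure=0.016, increments=5, cap_mode="axial_roller")
    sol = aw.newton_solve(mesh, mat, bc)
    oracle = aw.inflate_cylinder(aw.CylinderSpec(8.0, 10.0, 30.0, mat, 0.016))
    return {"solid": tube, "mesh": mesh, "mat": mat, "bc": bc, "sol": sol, "oracle": oracle}


@pytest.fixture(scope="session")
def thin_tube_case():
    """Thin-walled tube (R/t = 20) at low pressure for the membrane check."""
    mat = aw.REFERENT_NORMAL
    tube = aw.build_cylinder(19.0, 20.0, 40.0)
    mesh = aw.generate_mesh(tube, 2.0, resolution=(16, 40, 2))
    bc = aw.BoundaryConditions(pressure=0.002, increments=3, cap_mode="axial_roller")
    sol = aw.newton_solve(mesh, mat, bc)
    return {"solid": tube, "mesh": mesh, "mat": mat, "bc": bc, "sol": sol}


def hoop_stress(mesh, sol, region=None):
    """Element circumferential Cauchy stress (cylindrical rotation by centroid)."""
    cen = mesh.centroids if region is None else mesh.centroids[region]
    S = sol.stress if region is None else sol.stress[region]
    th = np.arctan2(cen[:, 1], cen[:, 0])
    et = np.stack([-np.sin(th), np.cos(th), np.zeros_like(th)], 1)
    return np.einsum("ei,eij,ej->e", et, S, et)
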