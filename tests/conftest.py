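"""Shared fixtures: small geometries and solved flow fields.

Flow solutions are session-scoped because each steady solve costs seconds;
tests treat them as read-only.
"""

import numpy as np
import pytest

from vffrcfd import (BoundaryConditions, FluidProperties, StenosisSpec,
                     build_mesh, make_stenosed_vessel, solve_steady)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def cylinder_geometry():
    spec = StenosisSpec(reference_diameter=3.0, stenosis_pct=0.0,
                        lesion_length=10.0, lesion_center=15.0,
                        vessel_length=30.0, case_id="cylinder")
    return make_stenosed_vessel(spec, 96, 48)


@pytest.fixture(scope="session")
def stenosed_geometry():
    spec = StenosisSpec(reference_diameter=3.0, stenosis_pct=60.0,
                        lesion_length=9.0, lesion_center=24.5,
                        vessel_length=30.0, case_id="sten60")
    return make_stenosed_vessel(spec, 96, 48)


@pytest.fixture(scope="session")
def cylinder_mesh(cylinder_geometry):
    return build_mesh(cylinder_geometry, 50)


@pytest.fixture(scope="session")
def stenosed_mesh(stenosed_geometry):
    return build_mesh(stenosed_geometry, 50)


@pytest.fixture(scope="session")
def cylinder_solution(cylinder_mesh, fluid):
    sol = solve_steady(cylinder_mesh, fluid,
                       BoundaryConditions(0.5, "parabolic"))
    assert sol.converged
    return sol


@pytest.fixture(scope="session")
def stenosed_pair(stenosed_mesh, fluid):
    """Solutions at the two characterization flows on one mesh."""
    low = solve_steady(stenosed_mesh, fluid, BoundaryConditions(1.0))
    high = solve_steady(stenosed_mesh, fluid, BoundaryConditions(3.0),
                        initial=low)
    assert low.converged and high.converged
    return low, high
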