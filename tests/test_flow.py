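"""Steady solver: analytic limits, conservation, convergence behaviour."""

import numpy as np
import pytest

from vffrcfd import (BoundaryConditions, FluidProperties, SolverControls,
                     SolverError, StenosisSpec, ValidationError, build_mesh,
                     fidelity_level, make_stenosed_vessel, poiseuille_oracle,
                     pressure_drop, reynolds_number, solve_steady,
                     stenosis_oracle)


class TestOracles:
    def test_poiseuille_hand_value(self):
        # 8 mu L Q / (pi R^4) at R=1.5 mm, L=30 mm, mu=3.5 mPa.s, Q=1 mL/s
        assert poiseuille_oracle(1.5, 30.0, 3.5e-3, 1.0) == pytest.approx(
            52.79, abs=0.05)

    def test_poiseuille_scalings(self):
        base = poiseuille_oracle(1.5, 30.0, 3.5e-3, 1.0)
        assert poiseuille_oracle(1.5, 30.0, 3.5e-3, 2.0) == pytest.approx(2 * base)
        assert poiseuille_oracle(3.0, 30.0, 3.5e-3, 1.0) == pytest.approx(base / 16)

    def test_poiseuille_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            poiseuille_oracle(0.0, 30.0, 3.5e-3, 1.0)

    def test_stenosis_oracle_limits(self, fluid):
        # zero stenosis: purely viscous, linear in flow
        a = stenosis_oracle(3.0, 0.0, 10.0, fluid, 1.0)
        b = stenosis_oracle(3.0, 0.0, 10.0, fluid, 2.0)
        assert b == pytest.approx(2 * a)
        # inertial term scales with U^2: dp(2Q) - 2 dp_viscous(Q) quadruples
        v1 = stenosis_oracle(3.0, 60.0, 10.0, fluid, 1.0, k_t=0.0)
        t1 = stenosis_oracle(3.0, 60.0, 10.0, fluid, 1.0) - v1
        t2 = stenosis_oracle(3.0, 60.0, 10.0, fluid, 2.0) - 2 * v1
        assert t2 == pytest.approx(4 * t1)


class TestCylinder:
    def test_parabolic_inlet_matches_poiseuille(self, cylinder_solution):
        s = cylinder_solution.section_arclength
        dp = pressure_drop(cylinder_solution, 0.0, s[-1])
        exact = poiseuille_oracle(1.5, s[-1], 3.5e-3, 0.5)
        assert dp == pytest.approx(exact, rel=0.05)

    def test_linear_pressure_gradient(self, cylinder_solution):
        # equal-length windows drop equal pressure in developed flow
        d1 = pressure_drop(cylinder_solution, 18.0, 23.0)
        d2 = pressure_drop(cylinder_solution, 23.0, 28.0)
        assert d1 == pytest.approx(d2, rel=0.03)

    def test_pressure_drop_identity_and_range(self, cylinder_solution):
        assert pressure_drop(cylinder_solution, 10.0, 10.0) == 0.0
        with pytest.raises(ValidationError):
            pressure_drop(cylinder_solution, -1.0, 10.0)
        with pytest.raises(ValidationError):
            pressure_drop(cylinder_solution, 20.0, 10.0)

    def test_mass_conservation(self, cylinder_solution, stenosed_pair):
        for sol in (cylinder_solution, *stenosed_pair):
            assert sol.metadata["mass_imbalance_rel"] < 1e-6
            assert sol.residual_history["continuity"].iloc[-1] < 1e-5

    def test_viscosity_scaling(self, cylinder_mesh, cylinder_solution, fluid):
        thick = FluidProperties(dynamic_viscosity=2 * fluid.dynamic_viscosity,
                                density=fluid.density)
        sol2 = solve_steady(cylinder_mesh, thick,
                            BoundaryConditions(0.5, "parabolic"))
        r = (pressure_drop(sol2, 2.0, 28.0)
             / pressure_drop(cylinder_solution, 2.0, 28.0))
        assert r == pytest.approx(2.0, rel=0.02)

    def test_near_zero_flow_is_rest_state(self, cylinder_mesh, fluid):
        sol = solve_steady(cylinder_mesh, fluid, BoundaryConditions(1e-7))
        assert sol.converged
        assert np.abs(sol.pressure).max() < 0.05      # Pa
        assert np.linalg.norm(sol.velocity, axis=1).max() < 1e-4

    def test_deterministic_fields(self, cylinder_mesh, fluid, cylinder_solution):
        again = solve_steady(cylinder_mesh, fluid,
                             BoundaryConditions(0.5, "parabolic"))
        assert np.array_equal(again.pressure, cylinder_solution.pressure)
        assert np.array_equal(again.velocity, cylinder_solution.velocity)

    def test_grid_convergence_of_pressure_drop(self, cylinder_geometry, fluid):
        bc = BoundaryConditions(0.5, "parabolic")
        drops = {}
        for p in (10, 25, 50, 75, 100):
            mesh = build_mesh(cylinder_geometry, p)
            sol = solve_steady(mesh, fluid, bc)
            assert sol.converged
            drops[p] = pressure_drop(sol, 2.0, 28.0)
        errs = [abs(drops[p] - drops[100]) for p in (10, 25, 50, 75)]
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))


class TestStenosed:
    def test_superlinear_pressure_flow(self, stenosed_pair):
        low, high = stenosed_pair
        dp1 = pressure_drop(low, 1.0, 29.0)
        dp3 = pressure_drop(high, 1.0, 29.0)
        assert dp3 / dp1 > 3.0     # inertial losses

    def test_lesion_window_dominates(self, stenosed_pair, stenosed_geometry):
        low, _ = stenosed_pair
        spec = stenosed_geometry.spec
        lesion = pressure_drop(low, spec.lesion_center - 4.5,
                               spec.lesion_center + 4.5)
        healthy = pressure_drop(low, 4.0, 13.0)
        assert lesion > healthy

    def test_solver_within_factor_two_of_stenosis_oracle(
            self, stenosed_pair, stenosed_geometry, fluid):
        _, high = stenosed_pair
        spec = stenosed_geometry.spec
        dp = pressure_drop(high, 1.0, 29.0)
        est = stenosis_oracle(spec.reference_diameter, spec.stenosis_pct,
                              spec.lesion_length, fluid, 3.0)
        assert est / 2 < dp < est * 2

    def test_reynolds_warning_recorded(self, stenosed_mesh, fluid):
        ctl = SolverControls(max_iter=5, stall_window=10 ** 9,
                             reynolds_cap=50.0)
        sol = solve_steady(stenosed_mesh, fluid, BoundaryConditions(3.0), ctl)
        assert any("Reynolds" in w for w in sol.metadata["warnings"])

    def test_warm_start_requires_same_mesh(self, stenosed_pair,
                                           cylinder_mesh, fluid):
        low, _ = stenosed_pair
        with pytest.raises(SolverError):
            solve_steady(cylinder_mesh, fluid, BoundaryConditions(3.0),
                         initial=low)

    def test_section_pressure_has_at_least_64_stations(self, stenosed_pair):
        low, _ = stenosed_pair
        assert len(low.section_arclength) >= 64
        assert np.all(np.diff(low.section_arclength) > 0)


def test_reynolds_number_value(fluid):
    # rho U D / mu with U = Q/A: hand-checked magnitude
    re = reynolds_number(1.0, 1.5, fluid)
    u = 1e-6 / (np.pi * 1.5e-3 ** 2)
    assert re == pytest.approx(1056 * u * 3e-3 / 3.5e-3)
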