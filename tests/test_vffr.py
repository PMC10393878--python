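"""Pressure-flow characterization and the vFFR operating point."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vffrcfd import (BoundaryConditions, PairingError, ValidationError,
                     build_mesh, compute_vffr_closed_form,
                     compute_vffr_pseudo_transient, fit_pressure_flow,
                     make_stenosed_vessel, solve_steady, StenosisSpec,
                     vffr_at, vffr_profile)


class TestFit:
    def test_hand_worked_example(self):
        # f + s = 10 and 3f + 9s = 42 eliminate to f=8, s=2
        c = fit_pressure_flow(1.0, 10.0, 3.0, 42.0)
        assert c.f == pytest.approx(8.0)
        assert c.s == pytest.approx(2.0)

    def test_pure_viscous_characteristic(self):
        c = fit_pressure_flow(1.0, 7.0, 3.0, 21.0)
        assert c.s == pytest.approx(0.0, abs=1e-12)
        assert c.f == pytest.approx(7.0)

    def test_zero_lesion(self):
        c = fit_pressure_flow(1.0, 0.0, 3.0, 0.0)
        assert c.f == 0.0 and c.s == 0.0

    def test_singular_system(self):
        with pytest.raises(ValidationError):
            fit_pressure_flow(2.0, 5.0, 2.0, 6.0)

    @settings(deadline=None, max_examples=200)
    @given(q1=st.floats(0.1, 10), dq=st.floats(0.1, 10),
           dp1=st.floats(-10, 200), dp2=st.floats(-10, 200))
    def test_exact_interpolation(self, q1, dq, dp1, dp2):
        q2 = q1 + dq
        c = fit_pressure_flow(q1, dp1, q2, dp2)
        assert c.dp(q1) == pytest.approx(dp1, rel=1e-9, abs=1e-9)
        assert c.dp(q2) == pytest.approx(dp2, rel=1e-9, abs=1e-9)


class TestOperatingPoint:
    def test_unobstructed_vessel(self):
        c = fit_pressure_flow(1.0, 0.0, 3.0, 0.0)
        r = compute_vffr_closed_form(c, Pa=100.0, R_mv=25.0)
        assert r.vffr == 1.0
        assert r.Q == pytest.approx(4.0)

    def test_huge_microvascular_resistance_limit(self):
        c = fit_pressure_flow(1.0, 10.0, 3.0, 42.0)
        r = compute_vffr_closed_form(c, Pa=100.0, R_mv=1e6)
        assert r.vffr == pytest.approx(1.0, abs=1e-4)

    def test_quadratic_root_hand_value(self):
        c = fit_pressure_flow(1.0, 10.0, 3.0, 42.0)
        r = compute_vffr_closed_form(c, Pa=100.0, R_mv=25.0)
        q_expected = (-33.0 + np.sqrt(1889.0)) / 4.0
        assert r.Q == pytest.approx(q_expected, rel=1e-12)
        assert r.vffr == pytest.approx(25.0 * q_expected / 100.0, rel=1e-12)
        assert r.Pd == pytest.approx(r.Pa - c.dp(r.Q), rel=1e-10)

    def test_pseudo_transient_single_step_linear(self):
        c = fit_pressure_flow(1.0, 0.0, 3.0, 0.0)
        r = compute_vffr_pseudo_transient(c, Pa=100.0, R_mv=25.0,
                                          relaxation=1.0)
        assert r.Q == pytest.approx(4.0)
        assert r.iterations <= 2

    def test_methods_agree_on_seeded_draws(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            f, s = rng.uniform(0, 50, 2)
            pa = rng.uniform(60, 140)
            rmv = rng.uniform(5, 100)
            c = fit_pressure_flow(1.0, f + s, 3.0, 3 * f + 9 * s)
            a = compute_vffr_closed_form(c, pa, rmv)
            b = compute_vffr_pseudo_transient(c, pa, rmv)
            assert abs(a.vffr - b.vffr) <= 1e-8 * a.vffr
            assert 0 < a.vffr <= 1

    def test_relaxation_changes_path_not_fixed_point(self):
        c = fit_pressure_flow(1.0, 10.0, 3.0, 42.0)
        slow = compute_vffr_pseudo_transient(c, relaxation=0.2)
        fast = compute_vffr_pseudo_transient(c, relaxation=0.9)
        assert slow.vffr == pytest.approx(fast.vffr, rel=1e-9)
        assert slow.iterations != fast.iterations

    def test_monotone_in_coefficients_and_resistance(self):
        base = compute_vffr_closed_form(fit_pressure_flow(1, 10, 3, 42))
        stiffer = compute_vffr_closed_form(fit_pressure_flow(1, 12, 3, 44))
        more_inertial = compute_vffr_closed_form(fit_pressure_flow(1, 11, 3, 47))
        assert stiffer.vffr < base.vffr          # larger f
        assert more_inertial.vffr < base.vffr    # larger s
        high_rmv = compute_vffr_closed_form(fit_pressure_flow(1, 10, 3, 42),
                                            R_mv=50.0)
        assert high_rmv.vffr > base.vffr

    def test_invalid_coupling_parameters(self):
        c = fit_pressure_flow(1.0, 1.0, 3.0, 4.0)
        with pytest.raises(ValidationError):
            compute_vffr_closed_form(c, Pa=-1.0)
        with pytest.raises(ValidationError):
            compute_vffr_pseudo_transient(c, relaxation=1.5)


class TestProfile:
    def test_inlet_station_is_unity(self, stenosed_pair):
        prof = vffr_profile(*stenosed_pair)
        assert prof["vffr"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_cylinder_profile_gently_non_increasing(self, cylinder_mesh,
                                                    fluid, cylinder_solution):
        high = solve_steady(cylinder_mesh, fluid,
                            BoundaryConditions(1.5, "parabolic"),
                            initial=None)
        prof = vffr_profile(cylinder_solution, high)
        v = prof["vffr"].to_numpy()
        assert np.all(np.diff(v) <= 0.005)
        assert v[-1] > 0.9          # healthy vessel stays near unity

    def test_throat_is_the_minimum_and_recovery_is_partial(
            self, stenosed_pair, stenosed_geometry):
        prof = vffr_profile(*stenosed_pair)
        spec = stenosed_geometry.spec
        s = prof["arclength_mm"].to_numpy()
        v = prof["vffr"].to_numpy()
        s_min = s[np.argmin(v)]
        assert abs(s_min - spec.lesion_center) < 3.0
        # distal values stay below every pre-lesion value: no full recovery
        pre = v[s < spec.lesion_center - spec.lesion_length / 2]
        post = v[s > spec.lesion_center + spec.lesion_length / 2]
        if len(post):
            assert post.max() < pre.min()

    def test_severity_monotonicity(self, fluid):
        values = {}
        for pct in (40.0, 75.0):
            spec = StenosisSpec(3.0, pct, 9.0, 24.5, 30.0)
            g = make_stenosed_vessel(spec, 64, 32)
            mesh = build_mesh(g, 25)
            low = solve_steady(mesh, fluid, BoundaryConditions(1.0))
            high = solve_steady(mesh, fluid, BoundaryConditions(3.0),
                                initial=low)
            prof = vffr_profile(low, high)
            values[pct] = vffr_at(prof, 28.5)
        assert values[75.0] < values[40.0]

    def test_profile_requires_matching_pair(self, stenosed_pair,
                                            cylinder_solution):
        low, high = stenosed_pair
        with pytest.raises(PairingError):
            vffr_profile(low, cylinder_solution)
        with pytest.raises(PairingError):
            vffr_profile(low, low)
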