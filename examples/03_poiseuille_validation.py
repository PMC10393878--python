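"""Validate the steady solver against the Hagen-Poiseuille closed form.

A straight tube with a fully developed (parabolic) inlet at Re~64 has the
exact solution dP = 8 mu L Q / (pi R^4); the finite-volume solution should
land within a fraction of a percent at full fidelity.
"""
from vffrcfd import (BoundaryConditions, FluidProperties, StenosisSpec,
                     build_mesh, make_stenosed_vessel, poiseuille_oracle,
                     pressure_drop, reynolds_number, solve_steady)

spec = StenosisSpec(3.0, 0.0, 10.0, 15.0, 30.0)
mesh = build_mesh(make_stenosed_vessel(spec), 100)
fluid = FluidProperties()
flow = 0.5  # mL/s
print(f"Re = {reynolds_number(flow, 1.5, fluid):.0f}")
sol = solve_steady(mesh, fluid, BoundaryConditions(flow, "parabolic"))
L = sol.section_arclength[-1]
dp = pressure_drop(sol, 0.0, L)
exact = poiseuille_oracle(1.5, L, fluid.dynamic_viscosity, flow)
print(f"solver dP = {dp:.2f} Pa, closed form = {exact:.2f} Pa, "
      f"error = {100 * abs(dp - exact) / exact:.2f}%")
print(f"converged in {sol.metadata['iterations']} iterations; "
      f"boundary mass imbalance {sol.metadata['mass_imbalance_rel']:.1e}")
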