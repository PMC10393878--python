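"""Mesh one vessel across the fidelity ladder and check volume convergence.

The fidelity slider maps geometrically onto a target cell count; the mesh
volume should approach the analytic tube volume as fidelity rises.
"""
from vffrcfd import (CANONICAL_FIDELITIES, StenosisSpec, analytic_volume,
                     build_mesh, make_stenosed_vessel, mesh_quality,
                     mesh_volume)

spec = StenosisSpec(3.0, 60.0, 10.0, 15.0, 30.0)
geometry = make_stenosed_vessel(spec)
exact = analytic_volume(geometry)
print("fidelity  cells   volume error   min scaled Jacobian")
for pct in CANONICAL_FIDELITIES:
    mesh = build_mesh(geometry, pct)
    err = abs(mesh_volume(mesh) - exact) / exact
    q = mesh_quality(mesh)
    print(f"  {pct:4d}%  {mesh.cell_count:6d}   {100 * err:9.3f}%   "
          f"{q.min_scaled_jacobian:.3f}")
# Volume error falls monotonically with fidelity; all cells stay valid
# (positive corner Jacobians) even through the throat.
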