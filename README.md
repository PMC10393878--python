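# vffrcfd

Desk-scale 3D computational-fluid-dynamics pipeline for **virtual
fractional flow reserve (vFFR)** on synthetic stenosed coronary vessels.

Fractional flow reserve — the ratio Pd/Pa of the pressure distal to a
coronary stenosis to the proximal (aortic) pressure under hyperaemia — is
the gold-standard index of whether a lesion warrants stenting
(FFR ≤ 0.80). Virtual FFR estimates it from 3D lumen anatomy by flow
computation instead of a pressure wire. This package implements the fast
protocol used by modern 3D-CFD vFFR systems, end to end, on parametric
synthetic vessels:

1. **Geometry** — cosine-tapered stenoses (30–90% diameter reduction, 2.5–4 mm
   vessels) as watertight STL surfaces with analytic centerline/radius
   ground truth.
2. **Meshing** — structured butterfly (O-H) hexahedral tube meshes with
   boundary-layer grading; a *fidelity* slider (1–100%) maps geometrically
   onto cell count, with five canonical levels (10/25/50/75/100%).
3. **Flow** — a pressure-based (SIMPLE) finite-volume solver for steady
   incompressible laminar Navier–Stokes: plug inlet, zero-pressure outlet,
   no-slip walls.
4. **vFFR** — two steady solves at Q = 1 and 3 mL/s determine the lesion's
   quadratic characteristic `ΔP(Q) = f·Q + s·Q²` (viscous + inertial, in
   mmHg and mL/s); coupling it to a lumped microvascular resistance
   (Pd = R_mv·Q, defaults Pa = 100 mmHg, R_mv = 25 mmHg/(mL/s)) gives the
   operating point `s·Q² + (f + R_mv)·Q − Pa = 0` and vFFR = Pd/Pa, by
   closed form and by the pseudo-transient iteration (required to agree to
   1e-8).
5. **Benchmarking** — a paired fidelity experiment against a 2×-finer
   reference arm: accuracy `(1 − |vFFR − vFFR_ref|/vFFR_ref)×100`,
   median/IQR summaries, exact Wilcoxon signed-rank contrasts with
   achievable-level confidence intervals, Bland–Altman limits of
   agreement, ANCOVA slope comparison, treat/defer concordance at
   vFFR ≤ 0.80.
6. **Energy** — constant-power energy/cost model (W × s → Wh → kWh) for
   simulation campaigns.

See `docs/methods.md` for the model details, numerical choices and
limitations; mesh sizes are deliberately desk-scale (hundreds to
thousands of cells), so the fidelity experiment reproduces qualitative
signatures, not production-CFD numbers.

## Worked example

```python
from vffrcfd import StenosisSpec, make_stenosed_vessel, simulate_vffr

spec = StenosisSpec(reference_diameter=3.0, stenosis_pct=60.0,
                    lesion_length=9.0, lesion_center=24.5,
                    vessel_length=30.0, case_id="demo60")
case = simulate_vffr(make_stenosed_vessel(spec), fidelity=100)
print(case.to_json_dict())
```

prints (abridged):

```
f    = 1.956   # viscous coefficient, mmHg/(mL/s)
s    = 3.323   # inertial coefficient, mmHg/(mL/s)^2
Q    = 2.766   # hyperaemic flow at the operating point, mL/s
Pd   = 69.16   # distal pressure, mmHg
vffr = 0.692   # Pd/Pa  ->  below 0.80: physiologically significant
```

The inertial term dominates this 60% lesion (s > f), the hyperaemic flow
is curtailed from the unobstructed ~4 mL/s to 2.77 mL/s, and the vFFR of
0.69 sits on the "treat" side of the 0.80 decision threshold. The
per-station profile (`case.profile`) equals 1.0 at the inlet, falls
gently along the healthy segment (viscous losses), and drops steeply
across the lesion to 0.69 at the distal measurement point.

The `examples/` directory holds one short script per capability
(geometry + STL round trip, mesh fidelity ladder, Poiseuille validation,
vFFR, the paired benchmark, energy costs). A thin CLI mirrors them:
`vffr synth`, `vffr mesh`, `vffr solve`, `vffr compute`,
`vffr benchmark`, `vffr cost` (see `--help`).

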