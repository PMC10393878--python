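# Methods

`vffrcfd` reimplements, at desk scale, a rapid 3D-CFD pipeline for virtual
fractional flow reserve (vFFR): two steady incompressible Navier–Stokes
solutions per vessel characterize the lesion's pressure–flow relation,
which is coupled to a lumped microvascular bed to yield the hyperaemic
operating point. Around the core sit a mesh-fidelity experiment, a paired
statistics harness, and a constant-power energy-cost model. Everything
runs on synthetic stenosed-vessel geometries with analytic oracles; no
clinical images are involved.

## Synthetic vessels

A vessel is a circular-cross-section tube swept along a straight or
circular-arc centerline. A stenosis is a raised-cosine narrowing of the
radius over a lesion window: C1-smooth, reference radius outside the
window, throat radius `r_ref (1 - pct/100)` exactly at the lesion center.
Eccentric lesions translate the lumen center radially by
`eccentricity x (r_ref - r(s))`, preserving cross-sectional area.
All geometry is in millimetres; SI conversion happens at the solver
boundary.

The default cohort (fixed seed 20230421) is 40 straight axisymmetric
vessels: percent diameter stenosis uniform in [30, 90], reference diameter
uniform in [2.5, 4.0] mm, lesion length uniform in [8, 12] mm, in a 30 mm
segment. The vessel is truncated 0.5–1.5 mm distal of the lesion end, as
when an angiographic reconstruction ends near the distal
pressure-measurement position. The truncation is also what makes a
*steady* laminar problem well posed across the severity range: with a long
distal runoff, the confined post-stenotic jet at the 3 mL/s
characterization flow is physically unsteady (the residual history orbits
a limit cycle rather than converging), whereas letting the shear layer
exit the domain restores a stable steady solution for all but the most
severe cases. What the synthetic cohort does *not* emulate: real lesion
morphology (eccentric, irregular, calcified), vessel taper, curvature,
side branches, and the pressure-recovery zone distal of the truncation —
so passing the sweep demonstrates solver/harness behaviour, not clinical
accuracy.

## Meshing and the fidelity slider

Meshes are structured butterfly (O-H) hexahedral grids: an `m x m` core
block plus `m` rings of `4m` cells (5 m² cells per section), swept along
`n_axial` stations; the three wall-adjacent rings are geometrically graded
(ratio 1.3) to resolve the viscous boundary layer. The wall polygon is
inflated so the inscribed cross-section preserves the disc area (a k-gon
at radius r has area (k/2) r² sin(2π/k)); without this, the effective
radius deficit biases viscous pressure drops by ~2%.

A fidelity percentage maps onto a target cell count geometrically:
`n(p) = n_min (n_max/n_min)^((p-1)/99)`. The desk-scale defaults are
n_min = 600 and n_max = 6,000 cells with a reference arm at 2 x n_max =
12,000 — chosen so that a 40-vessel x (5 fidelities + reference) x 2-flow
sweep completes in minutes in an interpreted solver while still spanning
an 10x resolution range; the absolute cell counts are far below
production CFD, so all fidelity-sweep results are scaled-down analogues,
not reproductions. Both `m` and `n_axial` grow monotonically with the
target count (floor for `m`, remainder into the axial direction), making
the fidelity ladder a nested-refinement family; an earlier chooser that
alternated section-heavy and axial-heavy allocations produced
non-monotone discretization error across the ladder and was replaced.
Meshing is deterministic and its time is excluded from benchmark
durations.

## Flow solver

Collocated finite-volume SIMPLE on the hex mesh:

* Convection: implicit first-order upwind; a deferred linear-upwind
  correction is available (`convection_blend`) but off by default — on
  post-stenotic jets the unlimited correction produces residual limit
  cycles, and for the quantities of interest (section-averaged pressure)
  the upwind scheme at the ladder's resolutions is the better-behaved
  choice.
* Diffusion: central with over-relaxed non-orthogonal decomposition; the
  tangential correction is applied explicitly from Green–Gauss gradients.
* Pressure–velocity coupling: Rhie–Chow interpolated face mass fluxes; the
  pressure-correction operator's interface coefficients are frozen at the
  first outer iteration so one exact sparse LU factorization serves the
  whole solve. The converged solution does not depend on those
  coefficients (the correction vanishes at convergence); they only shape
  the iteration path.
* Momentum inner solves: incomplete-LU-preconditioned refinement, with the
  preconditioner refreshed every 50 outer iterations (and whenever it
  demonstrably staled).
* Under-relaxation 0.7 (momentum) / 0.3 (pressure).
* Boundaries: plug or fully developed parabolic velocity inlet with the
  discrete influx normalized to the requested flow; uniform fixed-pressure
  outlet with Rhie–Chow dissipation (backflow carries zero momentum);
  no-slip walls.
* Initialization: per-layer 1D estimate (area-ratio velocity, Poiseuille +
  Bernoulli pressure); the high characterization flow warm-starts from the
  converged low-flow field, and a stalled low-flow solve is retried from a
  converged high-flow field (separated low-flow states sometimes settle
  only from a developed jet).

Convergence is declared when normalized residuals fall below 1e-5:
momentum residuals are scaled by the flow's own momentum turnover
Σ|a_P u_P| (the convention of pressure-based production solvers) and
continuity by the inlet mass flux. A stall detector returns flagged
(`converged=False`) solutions when residuals stop improving far from
tolerance; genuine blow-up raises. The flow is laminar throughout —
coronary Reynolds numbers at the protocol flows are a few hundred — and a
configurable cap (default 2000) records a metadata warning when throat
Reynolds numbers leave the regime where the laminar steady model is
credible. The solver is deterministic: fixed iteration order, direct
sparse solves, no randomness.

Fluid properties default to μ = 3.5 mPa·s, ρ = 1056 kg/m³ (conventional
blood-analog values; configurable). Walls are rigid, rheology Newtonian.

Validation anchors: on a straight tube with a parabolic inlet at Re ≈ 64
the full-fidelity solution lands within ~0.1% of the Hagen–Poiseuille
closed form (the 2% acceptance band is comfortable); with the protocol's
plug inlet the developing-flow region adds a genuine entrance pressure
drop, so plug-inlet checks use a downstream fully developed window. A
Young–Tsai-family viscous+inertial correlation provides an
order-of-magnitude band (factor two) for stenosed cases.

## vFFR

The translesional drop is characterized by `dP(Q) = f Q + s Q²`
(mmHg, mL/s) fitted exactly through the two steady solutions at 1 and
3 mL/s. Coupling to a proximal pressure `Pa` and a distal lumped
resistance `R_mv` (`Pd = R_mv Q`) gives
`s Q² + (f + R_mv) Q − Pa = 0`, `vFFR = Pd/Pa`. Two solvers are provided
and required to agree to 1e-8: the closed-form positive root and a
pseudo-transient under-relaxed fixed-point march whose default relaxation
comes from a contraction bound (`Q ≤ Pa/R_mv`), guaranteeing stability for
any physical curve. Defaults `Pa = 100 mmHg`, `R_mv = 25 mmHg/(mL/s)` put
an unobstructed vessel at ~4 mL/s hyperaemic flow and a mid-range 60%
lesion near the 0.80 decision threshold; both are conventions, not
patient-derived values. The conversion constant is 1 mmHg = 133.322 Pa.

vFFR is reported at a measurement point 10 mm distal of the lesion end,
clipped to at least 1 mm from the outlet (for the truncated cohort
vessels this lands just distal of the lesion, where a pressure wire would
sit). The per-station profile fits `(f, s)` independently at every
pressure station; it equals 1 at the inlet and dips to its minimum at the
throat. Distal of the throat the pressure partially recovers (a real
diffuser effect), so the profile is *not* monotone through a lesion —
only healthy tubes give a monotone gentle decline — but distal values
never exceed pre-lesion values (no full recovery).

## Benchmark statistics

The reference ("CPU-analog") arm is the same solver on the 2 x n_max
mesh; the fidelity arms play the reduced-resolution role. Accuracy is
`(1 − |vFFR − vFFR_ref| / vFFR_ref) x 100`. Cases whose reference or any
fidelity arm fails to converge are excluded entirely from paired analyses
and enumerated, keeping the design fully paired. Summaries are medians
with type-7 (linear interpolation) quartiles.

Paired contrasts use the Wilcoxon signed-rank test: exact distribution by
dynamic programming over (doubled) midranks for n ≤ 25, normal
approximation with tie and continuity corrections above. The primary
confidence interval of the median difference uses binomial order
statistics at the achievable level nearest the request — at n = 40 that
level is exactly 96.15% — with the Walsh-average (Hodges–Lehmann)
interval reported alongside. Bland–Altman limits are bias ± 1.96 x sample
SD (n−1). The severity–accuracy relation is ordinary least squares of
accuracy on reference vFFR per fidelity, with slope homogeneity tested by
the classic ANCOVA interaction F-test. Threshold concordance counts
agreement of the treat/defer classification at vFFR ≤ 0.80. The
"all reduced arms vs reference" duration contrast is ambiguous when each
case carries five fidelity durations; the harness pools every
(case, fidelity) pair with its case's reference by default and offers a
per-case-median pooling as an option.

## Energy model

Each arm draws a constant average power (50 W for a four-core CPU slice,
295 W for a GPU at its maximum rating — deliberately conservative in the
GPU's disfavour); energy per case is `P t / 3600` Wh and campaign cost
converts Wh to kWh explicitly before applying the tariff (1000 cases at
8.44 Wh and 0.25/kWh cost 2.11, i.e. 8.44 kWh total). A measured-power
table can replace the constants where instrumentation exists. At desk
scale the reference-vs-fidelity duration ratio is much smaller than in
production, so the energy *advantage* of the fast arm need not reproduce;
only the arithmetic and the rank structure are claimed.

## Numerical and degenerate-input choices

* Near-zero inflow solves converge to the rest state (uniform zero gauge
  pressure); inlet flow must be strictly positive.
* Two equal characterization flows make the 2x2 fit singular and raise.
* `f < 0` from discretization noise is flagged, not fatal; the operating
  point guard rejects curves with no positive root.
* STL is read and written in both binary and ASCII dialects; malformed
  binary payloads report the byte offset of the inconsistency. Surfaces
  must be watertight to be written or sliced.
* Cross-section pressures are volume-weighted means per axial cell layer,
  resampled onto ≥ 64 stations; plane cuts that intersect the surface in
  more than one loop (severe tortuosity) are an error, as is a centerline
  turning more than 45° between stations in the structured sweep.

## Known limitations

Steady laminar rigid-wall flow only; no transient, turbulence or
fluid–structure modelling. Severe lesions (throat Reynolds number beyond
the laminar cap, roughly > 80% stenosis in small vessels at 3 mL/s) do
not reach the 1e-5 residual contract and are excluded rather than
reported. Mesh resolution is orders of magnitude below production CFD;
fidelity-sweep numbers are qualitative signatures (monotone medians,
direction of the severity–accuracy relation), not clinical accuracy
claims. The microvascular resistance is a single global constant; no
patient personalization. Single lesions only — tandem disease is out of
scope.
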