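"""Steady incompressible Navier-Stokes on a tube mesh.

A pressure-based (SIMPLE family) finite-volume solver on the collocated
butterfly hex meshes of :mod:`vffrcfd.meshing`:

* momentum: implicit first-order upwind convection with a deferred
  linear-upwind (second-order) correction, central diffusion with explicit
  non-orthogonal correction, under-relaxed implicitly;
* continuity: Rhie-Chow interpolated face mass fluxes and a pressure
  correction equation whose interface coefficients are frozen at the first
  outer iteration, so one sparse LU factorization serves the whole solve
  (the converged solution does not depend on those coefficients -- they only
  shape the path to it);
* boundary conditions: plug (or fully developed parabolic) velocity inlet,
  uniform fixed-pressure outlet, no-slip walls.

Laminar throughout; coronary Reynolds numbers at the protocol flows are a
few hundred.  A configurable Reynolds cap flags (not models) flows beyond
the laminar assumption.  The solver is deterministic: fixed iteration
order, direct sparse solves, no randomness.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .errors import NonConvergenceError, SolverError, ValidationError
from .meshing import TubeMesh, cell_volumes
from .units import ML_S, MM

__all__ = [
    "FluidProperties",
    "BoundaryConditions",
    "SolverControls",
    "FlowSolution",
    "solve_steady",
    "pressure_drop",
    "poiseuille_oracle",
    "stenosis_oracle",
    "reynolds_number",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood-analog fluid. Defaults: mu = 3.5 mPa.s, rho = 1056 kg/m^3."""

    dynamic_viscosity: float = 3.5e-3   # Pa.s
    density: float = 1056.0             # kg/m^3

    def __post_init__(self):
        if self.dynamic_viscosity <= 0 or self.density <= 0:
            raise ValidationError("viscosity and density must be strictly positive")


@dataclass(frozen=True)
class BoundaryConditions:
    """Inlet volumetric flow (mL/s), inlet profile shape, gauge outlet pressure (Pa)."""

    inlet_flow: float                   # mL/s
    inlet_profile: str = "plug"         # "plug" | "parabolic"
    outlet_pressure: float = 0.0        # Pa

    def __post_init__(self):
        if self.inlet_flow <= 0:
            raise ValidationError(f"inlet_flow must be > 0 mL/s, got {self.inlet_flow}")
        if self.inlet_profile not in ("plug", "parabolic"):
            raise ValidationError(
                f"inlet_profile must be 'plug' or 'parabolic', got {self.inlet_profile!r}")


@dataclass(frozen=True)
class SolverControls:
    """Iteration controls of the SIMPLE loop.

    Normalized residuals below ``tol`` on all momentum components and
    continuity declare convergence.  A stall detector stops runs whose
    residuals stop improving (returned with ``converged=False``); genuine
    residual blow-up raises :class:`NonConvergenceError`.
    """

    urf_velocity: float = 0.7
    urf_pressure: float = 0.3
    tol: float = 1e-5
    max_iter: int = 800
    momentum_refinements: int = 2   # preconditioned refinement steps per outer iter
    momentum_lu_every: int = 50     # refactorize the momentum preconditioner
    convection_blend: float = 0.0   # deferred linear-upwind fraction in [0, 1]
    reynolds_cap: float = 2000.0
    stall_window: int = 80
    stall_factor: float = 0.95
    stall_floor: float = 1e-3      # residual level considered hopeless
    divergence_factor: float = 1e4


@dataclass
class FlowSolution:
    """Converged (or flagged) steady fields on one mesh.

    ``section_pressure`` is the volume-weighted cross-section average of the
    cell pressures in each axial layer, resampled on >= 64 stations.
    """

    velocity: np.ndarray            # (Nc, 3) m/s
    pressure: np.ndarray            # (Nc,) Pa
    residual_history: pd.DataFrame
    converged: bool
    section_arclength: np.ndarray   # (ns,) mm
    section_pressure: np.ndarray    # (ns,) Pa
    duration: float                 # wall seconds of the iteration loop
    metadata: dict = field(default_factory=dict)
    _phi: np.ndarray | None = None
    _phi_b: np.ndarray | None = None

    def section_pressure_at(self, s_mm):
        return np.interp(s_mm, self.section_arclength, self.section_pressure)


def reynolds_number(flow_ml_s: float, radius_mm: float, fluid: FluidProperties) -> float:
    """Tube Reynolds number rho U D / mu at the given flow and radius."""
    r = radius_mm * MM
    u = flow_ml_s * ML_S / (np.pi * r * r)
    return fluid.density * u * 2.0 * r / fluid.dynamic_viscosity


def poiseuille_oracle(radius_mm: float, length_mm: float,
                      viscosity_pa_s: float, flow_ml_s: float) -> float:
    """Hagen-Poiseuille pressure drop 8 mu L Q / (pi R^4), in Pa."""
    if min(radius_mm, length_mm, viscosity_pa_s, flow_ml_s) <= 0:
        raise ValidationError("all Poiseuille arguments must be positive")
    r, ln, q = radius_mm * MM, length_mm * MM, flow_ml_s * ML_S
    return 8.0 * viscosity_pa_s * ln * q / (np.pi * r ** 4)


def stenosis_oracle(reference_diameter_mm: float, stenosis_pct: float,
                    lesion_length_mm: float, fluid: FluidProperties,
                    flow_ml_s: float, k_v: float | None = None,
                    k_t: float = 1.52) -> float:
    """Viscous + inertial empirical stenosis pressure-drop estimate (Pa).

    Young-Tsai-family correlation
    ``dP = K_v (mu U / D0) (A0/At)^2 + K_t (rho/2) (A0/At - 1)^2 U^2``
    with U the reference-segment mean velocity.  ``K_v`` defaults to
    ``32 L / D0`` (a Poiseuille-like viscous factor over the lesion length);
    ``K_t = 1.52`` is the classical expansion-loss constant.  This is an
    order-of-magnitude sanity reference, not a solver substitute.
    """
    d0 = reference_diameter_mm * MM
    a_ratio = 1.0 / (1.0 - stenosis_pct / 100.0) ** 2   # A0 / At
    u0 = flow_ml_s * ML_S / (np.pi * (d0 / 2) ** 2)
    if k_v is None:
        k_v = 32.0 * (lesion_length_mm * MM) / d0
    viscous = k_v * fluid.dynamic_viscosity * u0 / d0 * a_ratio ** 2
    inertial = k_t * 0.5 * fluid.density * (a_ratio - 1.0) ** 2 * u0 ** 2
    return viscous + inertial


# ---------------------------------------------------------------------------
# geometric precompute


class _FvmOperator:
    """Face/cell geometry and sparse patterns for one mesh."""

    def __init__(self, mesh: TubeMesh):
        self.mesh = mesh
        nodes = mesh.nodes
        p = nodes[mesh.face_nodes]
        self.sf = 0.5 * np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 1])
        self.cf = p.mean(axis=1)
        self.area = np.linalg.norm(self.sf, axis=1)

        vol = cell_volumes(mesh)
        if vol.min() <= 0:
            raise SolverError("mesh contains non-positive cell volumes")
        self.vol = vol
        # volume-weighted cell centroids from face pyramids
        apex = nodes[mesh.cells].mean(axis=1)
        nc = mesh.cell_count
        cen = np.zeros((nc, 3))
        for cells_idx, sign in ((mesh.face_owner, 1.0),
                                (mesh.face_neigh, -1.0)):
            m = cells_idx >= 0
            ci = cells_idx[m]
            vp = sign * np.einsum("ij,ij->i", self.cf[m] - apex[ci], self.sf[m]) / 3.0
            pc = apex[ci] + 0.75 * (self.cf[m] - apex[ci])
            for k in range(3):
                cen[:, k] += np.bincount(ci, weights=vp * pc[:, k], minlength=nc)
        self.centroid = cen / vol[:, None]

        internal = mesh.face_neigh >= 0
        self.int_mask = internal
        self.fo = mesh.face_owner[internal]
        self.fn = mesh.face_neigh[internal]
        self.sfi = self.sf[internal]
        self.cfi = self.cf[internal]
        d = self.centroid[self.fn] - self.centroid[self.fo]
        sd = np.einsum("ij,ij->i", self.sfi, d)
        if sd.min() <= 0:
            raise SolverError("face orientation inconsistent with cell centroids")
        self.di = d
        self.gdiff = np.einsum("ij,ij->i", self.sfi, self.sfi) / sd
        self.tvec = self.sfi - self.gdiff[:, None] * d      # non-orthogonal part
        do = np.linalg.norm(self.cfi - self.centroid[self.fo], axis=1)
        dn = np.linalg.norm(self.cfi - self.centroid[self.fn], axis=1)
        self.gw = dn / (do + dn)                             # owner weight

        bmask = ~internal
        self.bo = mesh.face_owner[bmask]
        self.sfb = self.sf[bmask]
        self.cfb = self.cf[bmask]
        self.btag = mesh.face_tag[bmask]
        db = self.cfb - self.centroid[self.bo]
        self.gdiff_b = np.einsum("ij,ij->i", self.sfb, self.sfb) / np.maximum(
            np.einsum("ij,ij->i", self.sfb, db), 1e-300)
        self.inlet = self.btag == TubeMesh.INLET
        self.outlet = self.btag == TubeMesh.OUTLET
        self.wall = self.btag == TubeMesh.WALL

        # per-cell axial direction (top-cap centroid minus bottom-cap centroid)
        hx = nodes[mesh.cells]
        self.cell_axis = _normalize(hx[:, 4:8].mean(axis=1) - hx[:, 0:4].mean(axis=1))

        # CSR pattern shared by momentum and pressure matrices
        nfi = len(self.fo)
        rows = np.concatenate([np.arange(nc), self.fo, self.fn])
        cols = np.concatenate([np.arange(nc), self.fn, self.fo])
        marker = np.arange(1, len(rows) + 1, dtype=np.int64)
        csr = sp.coo_matrix((marker, (rows, cols)), shape=(nc, nc)).tocsr()
        gather = np.asarray(csr.data, dtype=np.int64) - 1
        self._csr_template = csr
        self._gather = gather
        self.nc = nc
        self.nfi = nfi

        # face -> cell incidence operators (owner, neighbour, owner-minus-
        # neighbour, boundary owner); all per-iteration scatters are sparse
        # matmuls through these
        ones = np.ones(nfi)
        self.So = sp.csr_matrix((ones, (self.fo, np.arange(nfi))), shape=(nc, nfi))
        self.Sn = sp.csr_matrix((ones, (self.fn, np.arange(nfi))), shape=(nc, nfi))
        self.Sd = (self.So - self.Sn).tocsr()
        nb = len(self.bo)
        self.Sb = sp.csr_matrix((np.ones(nb), (self.bo, np.arange(nb))),
                                shape=(nc, nb))

    def matrix(self, diag, a_on, a_no) -> sp.csr_matrix:
        """Assemble CSR with cached pattern: diag + one entry per face side."""
        values = np.concatenate([diag, a_on, a_no])
        A = self._csr_template.copy()
        A.data = values[self._gather]
        return A

    # -- Green-Gauss gradients ------------------------------------------------

    def grad_fields(self, fields, fields_b):
        """Gradients of K cell fields at once: (nc, K, 3) from (nc, K)."""
        face = (self.gw[:, None] * fields[self.fo]
                + (1.0 - self.gw)[:, None] * fields[self.fn])
        g = np.empty((self.nc, fields.shape[1], 3))
        for k in range(3):
            g[:, :, k] = (self.Sd @ (face * self.sfi[:, k, None])
                          + self.Sb @ (fields_b * self.sfb[:, k, None]))
        return g / self.vol[:, None, None]

    def grad_scalar(self, phi, phi_b):
        return self.grad_fields(phi[:, None], phi_b[:, None])[:, 0, :]


def _normalize(v):
    return v / np.maximum(np.linalg.norm(v, axis=-1, keepdims=True), 1e-300)


# ---------------------------------------------------------------------------
# boundary values


def _inlet_velocity(op: _FvmOperator, bc: BoundaryConditions):
    """Per-inlet-face velocity vectors with exactly the requested flux."""
    sf_in = op.sfb[op.inlet]
    cf_in = op.cfb[op.inlet]
    area = np.linalg.norm(sf_in, axis=1)
    normal_in = -_normalize(sf_in)          # into the domain
    q = bc.inlet_flow * ML_S
    if bc.inlet_profile == "plug":
        shape = np.ones(len(sf_in))
    else:
        a_tot = area.sum()
        center = (cf_in * area[:, None]).sum(axis=0) / a_tot
        r = np.linalg.norm(cf_in - center, axis=1)
        r_cap = np.sqrt(a_tot / np.pi)
        shape = np.maximum(1.0 - (r / r_cap) ** 2, 0.0)
    # u = c * shape * n_in with c chosen so the discrete influx is exactly q
    flux_shape = (shape * area).sum()
    return (q / flux_shape) * shape[:, None] * normal_in


# ---------------------------------------------------------------------------
# the SIMPLE loop


def solve_steady(mesh: TubeMesh, fluid: FluidProperties, bc: BoundaryConditions,
                 controls: SolverControls | None = None,
                 initial: FlowSolution | None = None) -> FlowSolution:
    """Iterate SIMPLE to a steady solution on ``mesh``.

    ``initial`` (a solution on the same mesh, typically at another flow rate)
    warm-starts the fields, scaled to the new flow.
    """
    ctl = controls or SolverControls()
    op = _FvmOperator(mesh)
    t0 = time.perf_counter()

    rho, mu = fluid.density, fluid.dynamic_viscosity
    q_si = bc.inlet_flow * ML_S
    mdot = rho * q_si

    u_in_faces = _inlet_velocity(op, bc)
    phi_in = rho * np.einsum("ij,ij->i", u_in_faces, op.sfb[op.inlet])  # < 0
    assert phi_in.sum() < 0

    # continuity residuals are scaled by the inlet mass flux; momentum
    # residuals by the flow's own momentum turnover sum |a_P u_P| (the
    # convention of pressure-based production solvers)

    u, p, phi, phi_b = _initial_fields(op, mesh, fluid, bc, initial)

    nfi, nc = op.nfi, op.nc
    hist = {k: [] for k in ("ux", "uy", "uz", "continuity")}
    converged = False
    lu_p = None
    lu_mom = None
    lu_mom_at = -1
    dP_cell = None
    df_face = None
    df_out = None
    best = np.inf
    best_at = 0

    # loop-invariant boundary assembly pieces
    D = mu * op.gdiff
    bi = op.bo[op.inlet]
    bw = op.bo[op.wall]
    bo_ = op.bo[op.outlet]
    diag_bound = (np.bincount(bw, weights=mu * op.gdiff_b[op.wall], minlength=nc)
                  + np.bincount(bi, weights=mu * op.gdiff_b[op.inlet], minlength=nc))
    win = mu * op.gdiff_b[op.inlet] - phi_in  # diffusion + explicit inflow convection
    b_inlet = np.zeros((nc, 3))
    for k in range(3):
        b_inlet[:, k] = np.bincount(bi, weights=win * u_in_faces[:, k], minlength=nc)
    db_out = op.cfb[op.outlet] - op.centroid[bo_]
    urf = ctl.urf_velocity

    for it in range(ctl.max_iter):
        u_b = _boundary_velocity(op, u, u_in_faces)
        p_b = _boundary_pressure(op, p, bc)
        grads = op.grad_fields(np.column_stack([p, u]),
                               np.column_stack([p_b, u_b]))
        gradp = grads[:, 0, :]
        gradu = grads[:, 1:4, :]

        # --- momentum coefficients -----------------------------------------
        F = phi
        fpos = np.maximum(F, 0.0)
        fneg = np.maximum(-F, 0.0)
        a_on = -(D + fneg)
        a_no = -(D + fpos)
        diag = op.So @ (D + fpos) + op.Sn @ (D + fneg) + diag_bound
        diag += np.bincount(bo_, weights=np.maximum(phi_b[op.outlet], 0.0),
                            minlength=nc)

        b = -gradp * op.vol[:, None] + b_inlet

        # explicit corrections: non-orthogonal diffusion (always) plus an
        # optional deferred linear-upwind convection blend
        gradf = (op.gw[:, None, None] * gradu[op.fo]
                 + (1 - op.gw)[:, None, None] * gradu[op.fn])
        corr = -mu * np.einsum("fcd,fd->fc", gradf, op.tvec)
        if ctl.convection_blend > 0.0:
            up = np.where(F >= 0, op.fo, op.fn)
            r_up = op.cfi - op.centroid[up]
            corr += (ctl.convection_blend * F)[:, None] * np.einsum(
                "fcd,fd->fc", gradu[up], r_up)
        b -= op.Sd @ corr

        # implicit under-relaxation
        diag_r = diag / urf
        b += ((1.0 - urf) / urf) * diag[:, None] * u

        A = op.matrix(diag_r, a_on, a_no)

        # residual of the un-relaxed momentum equations at the current field
        # (the under-relaxation terms in A and b cancel when evaluated at u)
        res_mom = np.abs(b - A @ u)
        mom_scale = np.maximum(np.abs(diag[:, None] * u).sum(axis=0), 1e-300)
        mom_norm = res_mom.sum(axis=0) / mom_scale

        # --- momentum solve: cached-ILU preconditioned refinement ----------
        if lu_mom is None or it < 3 or it - lu_mom_at >= ctl.momentum_lu_every:
            lu_mom = spla.spilu(A.tocsc(), drop_tol=1e-4, fill_factor=10.0)
            lu_mom_at = it
        x = u.copy()
        for _ in range(ctl.momentum_refinements):
            x = x + lu_mom.solve(b - A @ x)
        if np.abs(b - A @ x).sum() > res_mom.sum():
            # stale preconditioner: refactorize and redo
            lu_mom = spla.spilu(A.tocsc(), drop_tol=1e-4, fill_factor=10.0)
            lu_mom_at = it
            x = u.copy()
            for _ in range(ctl.momentum_refinements):
                x = x + lu_mom.solve(b - A @ x)
        u_star = x

        # --- Rhie-Chow face fluxes -----------------------------------------
        if df_face is None:
            dP_cell = op.vol / diag_r
            df_face = op.gw * dP_cell[op.fo] + (1 - op.gw) * dP_cell[op.fn]
            df_out = dP_cell[bo_]
            coef = rho * df_face * op.gdiff
            coef_out = rho * df_out * op.gdiff_b[op.outlet]
            diag_p = op.So @ coef + op.Sn @ coef + np.bincount(
                bo_, weights=coef_out, minlength=nc)
            Ap = op.matrix(diag_p, -coef, -coef)
            lu_p = spla.splu(Ap.tocsc(), permc_spec="MMD_AT_PLUS_A")

        uf = op.gw[:, None] * u_star[op.fo] + (1 - op.gw)[:, None] * u_star[op.fn]
        gpf = op.gw[:, None] * gradp[op.fo] + (1 - op.gw)[:, None] * gradp[op.fn]
        phi_star = (rho * np.einsum("ij,ij->i", uf, op.sfi)
                    - rho * df_face * op.gdiff
                    * (p[op.fn] - p[op.fo] - np.einsum("ij,ij->i", gpf, op.di)))

        phi_b = np.zeros(len(op.bo))
        phi_b[op.inlet] = phi_in
        # outlet: advected flux plus Rhie-Chow dissipation against the fixed
        # outlet pressure (momentum of any backflow is treated as zero)
        phi_b[op.outlet] = (
            rho * np.einsum("ij,ij->i", u_star[bo_], op.sfb[op.outlet])
            - rho * df_out * op.gdiff_b[op.outlet]
            * (bc.outlet_pressure - p[bo_]
               - np.einsum("ij,ij->i", gradp[bo_], db_out)))

        # --- pressure correction -------------------------------------------
        div = op.Sd @ phi_star + op.Sb @ phi_b
        cont_norm = np.abs(div).sum() / mdot
        pprime = lu_p.solve(-div)

        # --- corrections ----------------------------------------------------
        p = p + ctl.urf_pressure * pprime
        ppb = np.where(op.outlet, 0.0, pprime[op.bo])
        gradpp = op.grad_scalar(pprime, ppb)
        u = u_star - dP_cell[:, None] * gradpp
        phi = phi_star + rho * df_face * op.gdiff * (pprime[op.fo] - pprime[op.fn])
        phi_b[op.outlet] = phi_b[op.outlet] + rho * df_out \
            * op.gdiff_b[op.outlet] * pprime[bo_]

        hist["ux"].append(mom_norm[0])
        hist["uy"].append(mom_norm[1])
        hist["uz"].append(mom_norm[2])
        hist["continuity"].append(cont_norm)

        worst = max(mom_norm.max(), cont_norm)
        if not np.isfinite(worst) or (it > 5 and worst > ctl.divergence_factor *
                                      max(hist["continuity"][0], 1e-3)):
            raise NonConvergenceError(
                f"residuals diverged at iteration {it} (value {worst:.3e})",
                residual_history=pd.DataFrame(hist))
        if worst < best * ctl.stall_factor:
            best = worst
            best_at = it
        if worst < ctl.tol and it > 2:
            converged = True
            break
        # stalled far from tolerance, or stuck for a very long time
        if it - best_at > ctl.stall_window and best > ctl.stall_floor:
            break
        if it - best_at > 4 * ctl.stall_window:
            break

    duration = time.perf_counter() - t0
    sec_s, sec_p = _section_pressure(op, mesh, p)
    re_in = reynolds_number(bc.inlet_flow, mesh.station_radius_mm[0], fluid)
    re_throat = reynolds_number(bc.inlet_flow, mesh.station_radius_mm.min(), fluid)
    warnings = []
    if max(re_in, re_throat) > ctl.reynolds_cap:
        warnings.append(
            f"Reynolds number {max(re_in, re_throat):.0f} exceeds laminar cap "
            f"{ctl.reynolds_cap:.0f}; laminar model retained")
    hist_df = pd.DataFrame(hist)
    boundary_net = phi_in.sum() + phi_b[op.outlet].sum()
    meta = {
        "iterations": len(hist_df),
        "reynolds_inlet": re_in,
        "reynolds_throat": re_throat,
        "warnings": warnings,
        "mesh_signature": mesh.signature(),
        "inlet_flow": bc.inlet_flow,
        "mass_imbalance_rel": abs(boundary_net) / mdot,
        "final_residual": float(max(hist_df.iloc[-1])) if len(hist_df) else np.nan,
    }
    return FlowSolution(velocity=u, pressure=p, residual_history=hist_df,
                        converged=converged, section_arclength=sec_s,
                        section_pressure=sec_p, duration=duration,
                        metadata=meta, _phi=phi, _phi_b=phi_b)


def _boundary_velocity(op, u, u_in_faces):
    ub = u[op.bo].copy()
    ub[op.wall] = 0.0
    ub[op.inlet] = u_in_faces
    return ub


def _boundary_pressure(op, p, bc):
    pb = p[op.bo].copy()
    pb[op.outlet] = bc.outlet_pressure
    return pb


def _initial_fields(op, mesh, fluid, bc, initial):
    rho = fluid.density
    q = bc.inlet_flow * ML_S
    if initial is not None:
        if initial.metadata.get("mesh_signature") != mesh.signature():
            raise SolverError("warm-start solution comes from a different mesh")
        scale = bc.inlet_flow / initial.metadata["inlet_flow"]
        return (initial.velocity * scale, initial.pressure * scale,
                initial._phi * scale, initial._phi_b * scale)

    layer = mesh.cell_layer
    n_ax = mesh.n_axial
    ds = np.diff(mesh.station_arclength_mm) * MM
    vol_layer = np.bincount(layer, weights=op.vol, minlength=n_ax)
    a_layer = vol_layer / ds
    u_ax = q / a_layer
    u0 = u_ax[layer][:, None] * op.cell_axis

    # 1D pressure estimate: Poiseuille gradient + Bernoulli, datum 0 at outlet
    r_eff = np.sqrt(a_layer / np.pi)
    dp_visc = 8.0 * fluid.dynamic_viscosity * q * ds / (np.pi * r_eff ** 4)
    p_stations = np.concatenate([np.cumsum(dp_visc[::-1])[::-1], [0.0]])
    p_layer = 0.5 * (p_stations[:-1] + p_stations[1:])
    p_layer = p_layer + 0.5 * rho * (u_ax[-1] ** 2 - u_ax ** 2)
    p0 = p_layer[layer]

    uf = op.gw[:, None] * u0[op.fo] + (1 - op.gw)[:, None] * u0[op.fn]
    phi0 = rho * np.einsum("ij,ij->i", uf, op.sfi)
    phi_b = np.zeros(len(op.bo))
    u_in_faces = _inlet_velocity(op, bc)
    phi_b[op.inlet] = rho * np.einsum("ij,ij->i", u_in_faces, op.sfb[op.inlet])
    out = rho * np.einsum("ij,ij->i", u0[op.bo[op.outlet]], op.sfb[op.outlet])
    phi_b[op.outlet] = out * (-phi_b[op.inlet].sum() / max(out.sum(), 1e-300))
    return u0, p0, phi0, phi_b


def _section_pressure(op, mesh, p):
    n_ax = mesh.n_axial
    vol = op.vol
    num = np.bincount(mesh.cell_layer, weights=p * vol, minlength=n_ax)
    den = np.bincount(mesh.cell_layer, weights=vol, minlength=n_ax)
    p_layer = num / den
    s_layer = mesh.layer_arclength_mm
    n_st = max(64, n_ax + 1)
    s_out = np.linspace(0.0, mesh.station_arclength_mm[-1], n_st)
    return s_out, np.interp(s_out, s_layer, p_layer)


def pressure_drop(solution: FlowSolution, s_proximal: float, s_distal: float) -> float:
    """Section-averaged pressure drop P(s_proximal) - P(s_distal), in Pa.

    May be negative across a pressure-recovery region downstream of a
    stenosis throat.
    """
    s = solution.section_arclength
    if not (s[0] <= s_proximal <= s[-1]) or not (s[0] <= s_distal <= s[-1]):
        raise ValidationError(
            f"stations [{s_proximal}, {s_distal}] outside vessel [{s[0]}, {s[-1]}] mm")
    if s_proximal > s_distal:
        raise ValidationError("require s_proximal <= s_distal")
    return float(solution.section_pressure_at(s_proximal)
                 - solution.section_pressure_at(s_distal))
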