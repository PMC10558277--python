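"""Two-phase Darcy flow of blood and an injected oily bolus in porous tissue.

The pore space holds two incompressible, immiscible phases — resident blood
and the injected DCACl/oil bolus — whose saturations sum to one. Each phase
follows Darcy's law with linear relative permeability (phase mobility
``lambda_i = s_i * kappa_i / mu_i``); the phase pressures differ by a
Brooks–Corey capillary pressure ``pc = pd / s_blood`` (pore-size index 1,
regularized by a saturation floor). Eliminating the bolus pressure gives
one elliptic equation for the blood pressure whose source is the volume
change of the hydrolysis mass exchange, plus a hyperbolic–parabolic mass
balance for the bolus saturation.

Discretization: cell-centered finite volumes with two-point flux and
harmonic-mean face mobilities for the pressure equation. The saturation is
advanced in fractional-flow form: the bolus flux is written as
``f_o(s) * v_T - D(s) grad s`` with ``f_o = lambda_o / (lambda_o +
lambda_b)`` the bolus fractional flow, ``v_T`` the total Darcy flux taken
face-wise consistent with the discrete pressure equation, and ``D =
(lambda_o lambda_b / lambda_T) dpc/ds`` the capillary diffusivity. Backward
Euler with first-order upwinding of ``f_o`` (Newton with backtracking for
the nonlinearity) keeps the saturation in [0, 1] for any time step.

During injection the vessel faces hold a Dirichlet injection pressure and
admit pure bolus (saturation ``s0``); far faces hold atmospheric pressure.
When the delivery window closes, convective transport stops (see the
simulator module).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .chemistry import ParameterSet, ParameterError
from .geometry import BoundaryTag, StructuredMesh
from . import _linalg

__all__ = [
    "FlowState",
    "FlowSolverError",
    "TimeStepError",
    "capillary_pressure",
    "capillary_diffusivity",
    "mobility",
    "fractional_flow",
    "solve_pressure",
    "darcy_velocity",
    "advance_saturation",
    "compute_flow_state",
    "quiescent_state",
]

S_MIN = 1e-3  # saturation floor bounding the capillary pressure
NEWTON_ATOL = 1e-10
NEWTON_RTOL = 1e-8
NEWTON_MAXIT = 25


class FlowSolverError(RuntimeError):
    """Raised when the pressure system is singular or the solve diverges."""


class TimeStepError(RuntimeError):
    """Raised when an implicit step fails; the caller may retry with dt/2."""


@dataclass
class FlowState:
    """Flow unknowns and derived fields at one time level.

    Cell fields: blood/bolus pressures (Pa), saturations (``s_bolus +
    s_blood = 1``), capillary pressure (Pa, ``p_bolus - p_blood``), phase
    mobilities (m^2/Pa/s). Face fields (signed normal components, m/s,
    superficial): total Darcy flux ``v_total`` consistent with the discrete
    pressure equation, and its phase split ``v_blood``/``v_bolus`` (the
    bolus flux includes the capillary-diffusion contribution).
    """

    p_blood: np.ndarray
    p_bolus: np.ndarray
    s_bolus: np.ndarray
    s_blood: np.ndarray
    pc: np.ndarray
    lambda_blood: np.ndarray
    lambda_bolus: np.ndarray
    v_blood: np.ndarray
    v_bolus: np.ndarray
    v_total: np.ndarray


def capillary_pressure(
    s_blood: np.ndarray | float, pd: float, s_min: float = S_MIN
) -> np.ndarray:
    """Brooks–Corey capillary pressure ``pc = pd / max(s_blood, s_min)``.

    Monotone non-increasing in blood saturation with ``pc(1) = pd``; the
    floor caps it at ``pd / s_min`` as the blood is fully displaced.
    """
    s = np.asarray(s_blood, dtype=float)
    return pd / np.maximum(s, s_min)


def mobility(s: np.ndarray | float, kappa: float, mu: float) -> np.ndarray:
    """Phase mobility ``lambda = s * kappa / mu`` (linear relative perm)."""
    if mu <= 0:
        raise ParameterError(f"viscosity must be positive, got {mu}")
    return np.asarray(s, dtype=float) * kappa / mu


def fractional_flow(s_bolus: np.ndarray | float, params: ParameterSet):
    """Bolus fractional flow ``f_o = lambda_o / (lambda_o + lambda_b)``
    and its saturation derivative.

    With linear mobilities, ``f_o' = a*b / lambda_T^2 >= 0`` where
    ``a = kappa_o/mu_o`` and ``b = kappa_b/mu_b``; monotone, with
    ``f_o(0) = 0`` and ``f_o(1) = 1``.
    """
    s = np.asarray(s_bolus, dtype=float)
    a = params.kappa_bolus / params.mu_bolus
    b = params.kappa_blood / params.mu_blood
    lam_t = s * a + (1.0 - s) * b
    f = s * a / lam_t
    df = a * b / lam_t**2
    return f, df


def capillary_diffusivity(
    s_bolus: np.ndarray | float, params: ParameterSet, s_min: float = S_MIN
) -> np.ndarray:
    """Capillary diffusivity ``D = (lambda_o lambda_b / lambda_T) dpc/ds``.

    With ``pc = pd/(1-s)``, ``dpc/ds = pd/(1-s)^2``, capped to zero where
    the saturation floor caps the capillary pressure; D vanishes at both
    saturation endpoints.
    """
    s = np.asarray(s_bolus, dtype=float)
    s_b = 1.0 - s
    lam_o = mobility(s, params.kappa_bolus, params.mu_bolus)
    lam_b = mobility(s_b, params.kappa_blood, params.mu_blood)
    lam_t = lam_o + lam_b
    dpc_ds = np.where(s_b > s_min, params.pd / np.maximum(s_b, s_min) ** 2, 0.0)
    return lam_o * lam_b / lam_t * dpc_ds


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def pressure_dirichlet(
    mesh: StructuredMesh,
    params: ParameterSet,
    bc,
    t: float,
    sealed_far: bool = False,
) -> np.ndarray:
    """Per-face Dirichlet blood pressure (NaN for interior/no-flow faces).

    VESSEL faces hold the injection pressure while the schedule is active
    and become no-flow afterwards (or atmospheric, when the schedule's
    ``post_injection`` mode is ``"p0"``); FAR faces hold atmospheric
    pressure unless the domain is sealed.
    """
    pb = np.full(mesh.n_faces, np.nan)
    far = mesh.boundary_faces(BoundaryTag.FAR)
    vessel = mesh.boundary_faces(BoundaryTag.VESSEL)
    if not sealed_far:
        pb[far] = params.p0
    if bc is not None:
        if bc.active(t):
            pb[vessel] = bc.p_injection
        elif getattr(bc, "post_injection", "noflow") == "p0":
            pb[vessel] = params.p0
    return pb


def assemble_pressure_system(
    mesh: StructuredMesh,
    s_bolus: np.ndarray,
    params: ParameterSet,
    p_bc: np.ndarray,
):
    """Sparse system ``A p_blood = b`` for the total-pressure equation.

    Two-point flux with harmonic-mean total mobility; the capillary term
    ``div(lambda_bolus grad pc)`` is evaluated from the current saturation
    and moved to the right-hand side; the hydrolysis volume source is
    ``gamma*rho_DCACl*eps*phi*s*(1/rho_blood - 1/rho_bolus)``. The
    capillary gradient is taken as zero across boundary faces.
    """
    s_o = np.asarray(s_bolus, dtype=float)
    s_b = 1.0 - s_o
    lam_b = mobility(s_b, params.kappa_blood, params.mu_blood)
    lam_o = mobility(s_o, params.kappa_bolus, params.mu_bolus)
    lam_t = lam_b + lam_o
    pc = capillary_pressure(s_b, params.pd)

    n = mesh.n_cells
    V = mesh.cell_volume
    rows, cols, vals = [], [], []
    b = np.zeros(n)

    b += V * (
        params.gamma * params.rho_dcacl * params.epsilon * params.phi * s_o
        * (1.0 / params.rho_blood - 1.0 / params.rho_bolus)
    )

    interior = mesh.interior
    own = mesh.face_owner[interior]
    nbr = mesh.face_neighbor[interior]
    geom = mesh.face_area[interior] / mesh.face_dist[interior]
    T = _harmonic(lam_t[own], lam_t[nbr]) * geom
    rows += [own, own, nbr, nbr]
    cols += [own, nbr, nbr, own]
    vals += [T, -T, T, -T]

    Tc = _harmonic(lam_o[own], lam_o[nbr]) * geom
    dpc = pc[nbr] - pc[own]
    np.add.at(b, own, Tc * dpc)
    np.add.at(b, nbr, -Tc * dpc)

    dir_faces = np.flatnonzero(~np.isnan(p_bc))
    if len(dir_faces):
        fo = mesh.face_owner[dir_faces]
        Tb = lam_t[fo] * mesh.face_area[dir_faces] / mesh.face_dist[dir_faces]
        rows.append(fo)
        cols.append(fo)
        vals.append(Tb)
        np.add.at(b, fo, Tb * p_bc[dir_faces])

    A = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return A, b, len(dir_faces) > 0


def solve_pressure(
    mesh: StructuredMesh,
    s_bolus: np.ndarray,
    params: ParameterSet,
    bc,
    t: float,
    sealed_far: bool = False,
) -> np.ndarray:
    """Solve the discrete total-pressure equation for the blood pressure.

    With no Dirichlet face anywhere (sealed domain) the system is pure
    Neumann; one cell is pinned to atmospheric pressure as gauge. Raises
    :class:`FlowSolverError` when the system is singular (e.g. vanishing
    total mobility everywhere).
    """
    p_bc = pressure_dirichlet(mesh, params, bc, t, sealed_far=sealed_far)
    A, b, has_dirichlet = assemble_pressure_system(mesh, s_bolus, params, p_bc)
    if not has_dirichlet:
        A = A.tolil()
        A.rows[0] = [0]
        A.data[0] = [1.0]
        b[0] = params.p0
        A = A.tocsr()
    if A.diagonal().max() <= 0:
        raise FlowSolverError("singular pressure system: zero total mobility")
    p = _linalg.solve(A, b, x0=np.full(mesh.n_cells, params.p0))
    if not np.all(np.isfinite(p)):
        raise FlowSolverError("pressure solve produced non-finite values")
    res = np.linalg.norm(A @ p - b)
    scale = max(np.linalg.norm(b), 1.0)
    if res > 1e-6 * scale:
        raise FlowSolverError(f"pressure residual {res:.2e} above tolerance")
    return p


def total_face_flux(
    mesh: StructuredMesh,
    p_blood: np.ndarray,
    s_bolus: np.ndarray,
    params: ParameterSet,
    p_bc: np.ndarray,
) -> np.ndarray:
    """Total Darcy flux per face, discretely consistent with the pressure
    equation (so cellwise flux divergence equals the hydrolysis volume
    source to solver tolerance)."""
    s_o = np.asarray(s_bolus, dtype=float)
    s_b = 1.0 - s_o
    lam_b = mobility(s_b, params.kappa_blood, params.mu_blood)
    lam_o = mobility(s_o, params.kappa_bolus, params.mu_bolus)
    lam_t = lam_b + lam_o
    pc = capillary_pressure(s_b, params.pd)

    vt = np.zeros(mesh.n_faces)
    own = mesh.face_owner
    nbr = mesh.face_neighbor
    i = np.flatnonzero(mesh.interior)
    inv_d = 1.0 / mesh.face_dist[i]
    vt[i] = -(
        _harmonic(lam_t[own[i]], lam_t[nbr[i]]) * (p_blood[nbr[i]] - p_blood[own[i]])
        + _harmonic(lam_o[own[i]], lam_o[nbr[i]]) * (pc[nbr[i]] - pc[own[i]])
    ) * inv_d

    bdir = np.flatnonzero(~np.isnan(p_bc))
    if len(bdir):
        vt[bdir] = -lam_t[own[bdir]] * (
            p_bc[bdir] - p_blood[own[bdir]]
        ) / mesh.face_dist[bdir]
    return vt


def _upwind_saturation(
    mesh: StructuredMesh,
    v: np.ndarray,
    s: np.ndarray,
    inflow_vessel: float,
    inflow_far: float,
) -> np.ndarray:
    """Face saturation upwinded by the sign of the face flux (arithmetic
    mean on ties; inflow boundaries carry the inflow composition)."""
    own = mesh.face_owner
    nbr = mesh.face_neighbor
    s_up = np.empty(mesh.n_faces)
    i = np.flatnonzero(mesh.interior)
    s_up[i] = np.where(
        v[i] > 0, s[own[i]], np.where(v[i] < 0, s[nbr[i]],
                                      0.5 * (s[own[i]] + s[nbr[i]]))
    )
    for tag, s_in in ((BoundaryTag.VESSEL, inflow_vessel),
                      (BoundaryTag.FAR, inflow_far)):
        f = mesh.boundary_faces(tag)
        s_up[f] = np.where(v[f] >= 0, s[own[f]], s_in)
    return s_up


def darcy_velocity(
    mesh: StructuredMesh,
    p_blood: np.ndarray,
    s_bolus: np.ndarray,
    params: ParameterSet,
    p_bc: np.ndarray,
):
    """Per-face phase Darcy fluxes from a solved blood-pressure field.

    Returns ``(v_blood, v_bolus, v_total)``: signed normal components
    along each face normal, superficial (mobility-weighted) velocities.
    The bolus flux is the fractional-flow split of the total flux,
    ``v_bolus = f_o(s_up) v_T - D_face ds/d`` with the face saturation
    upwinded by the sign of ``v_T`` and harmonic-mean capillary
    diffusivity (zero across boundary faces); the blood flux is the
    remainder ``v_T - v_bolus``. Uniform pressure and saturation give zero
    everywhere; flipping the sign of the pressure gradient flips every
    velocity.
    """
    s_o = np.asarray(s_bolus, dtype=float)
    vt = total_face_flux(mesh, p_blood, s_o, params, p_bc)
    s_up = _upwind_saturation(mesh, vt, s_o, params.s0, inflow_far=0.0)
    f_up, _ = fractional_flow(s_up, params)
    v_o = f_up * vt

    own = mesh.face_owner
    nbr = mesh.face_neighbor
    i = np.flatnonzero(mesh.interior)
    D = capillary_diffusivity(s_o, params)
    Df = _harmonic(D[own[i]], D[nbr[i]])
    v_o[i] -= Df * (s_o[nbr[i]] - s_o[own[i]]) / mesh.face_dist[i]
    return vt - v_o, v_o, vt


def compute_flow_state(
    mesh: StructuredMesh,
    s_bolus: np.ndarray,
    params: ParameterSet,
    bc,
    t: float,
    sealed_far: bool = False,
) -> FlowState:
    """Solve pressure and reconstruct all flow fields at time ``t``."""
    p = solve_pressure(mesh, s_bolus, params, bc, t, sealed_far=sealed_far)
    p_bc = pressure_dirichlet(mesh, params, bc, t, sealed_far=sealed_far)
    v_b, v_o, vt = darcy_velocity(mesh, p, s_bolus, params, p_bc)
    s_o = np.asarray(s_bolus, dtype=float)
    s_b = 1.0 - s_o
    pc = capillary_pressure(s_b, params.pd)
    return FlowState(
        p_blood=p, p_bolus=p + pc, s_bolus=s_o, s_blood=s_b, pc=pc,
        lambda_blood=mobility(s_b, params.kappa_blood, params.mu_blood),
        lambda_bolus=mobility(s_o, params.kappa_bolus, params.mu_bolus),
        v_blood=v_b, v_bolus=v_o, v_total=vt,
    )


def quiescent_state(
    mesh: StructuredMesh, s_bolus: np.ndarray, params: ParameterSet
) -> FlowState:
    """Flow state with zero velocities and uniform atmospheric pressure.

    Used after the delivery window closes (convective transport stops when
    the injection pressure is removed) and for reaction-only diagnostics.
    """
    s_o = np.asarray(s_bolus, dtype=float)
    s_b = 1.0 - s_o
    pc = capillary_pressure(s_b, params.pd)
    zf = np.zeros(mesh.n_faces)
    p = np.full(mesh.n_cells, params.p0)
    return FlowState(
        p_blood=p, p_bolus=p + pc, s_bolus=s_o, s_blood=s_b, pc=pc,
        lambda_blood=mobility(s_b, params.kappa_blood, params.mu_blood),
        lambda_bolus=mobility(s_o, params.kappa_bolus, params.mu_bolus),
        v_blood=zf.copy(), v_bolus=zf.copy(), v_total=zf.copy(),
    )


def advance_saturation(
    state: FlowState,
    mesh: StructuredMesh,
    params: ParameterSet,
    bc,
    dt: float,
    transport: bool = True,
):
    """Backward-Euler update of the bolus saturation over ``dt``.

    Solves the implicit fractional-flow mass balance

    ``phi ds/dt + div( f_o(s) v_T - D grad s ) = q_bolus / rho_bolus``

    with the total face flux ``v_T`` frozen from the current flow state
    (operator splitting), ``f_o`` upwinded by the sign of ``v_T`` and
    treated implicitly by Newton iteration with backtracking, the
    capillary diffusivity ``D`` lagged at the old saturation, and the
    hydrolysis sink implicit. The upwind M-matrix structure keeps ``s``
    in [0, 1] for any ``dt``; inflow faces carry the inflow composition
    (``s0`` at VESSEL faces, pure blood at FAR faces).

    Returns ``(s_new, diagnostics)`` where diagnostics hold the boundary
    bolus volume influx rate (m^3/s, net into the domain, evaluated at the
    new saturation), the reacted bolus mass rate (kg/s), the Newton
    iteration count and the final residual norm.

    With ``transport=False`` (delivery stasis: all Darcy and capillary
    fluxes are shut off once the injection pressure is removed) only the
    implicit reaction ODE is integrated per cell.

    Raises :class:`TimeStepError` on Newton non-convergence.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    s_old = state.s_bolus
    n = mesh.n_cells
    V = mesh.cell_volume

    if not transport:
        react = (
            params.gamma * params.rho_dcacl * params.epsilon * params.phi
            / params.rho_bolus
        )
        s = s_old * (params.phi / dt) / (params.phi / dt + react)
        reacted_rate = float(
            (params.gamma * params.rho_dcacl * params.epsilon * params.phi
             * s * V).sum()
        )
        return s, {
            "boundary_bolus_volume_rate": 0.0,
            "reacted_mass_rate": reacted_rate,
            "residual": 0.0,
            "newton_iterations": 0,
        }

    vt = state.v_total
    A_f = mesh.face_area
    own = mesh.face_owner
    nbr = mesh.face_neighbor

    react = (
        params.gamma * params.rho_dcacl * params.epsilon * params.phi
        / params.rho_bolus
    )

    i = np.flatnonzero(mesh.interior)
    D = capillary_diffusivity(s_old, params)
    TD = _harmonic(D[own[i]], D[nbr[i]]) * A_f[i] / mesh.face_dist[i]

    vessel = mesh.boundary_faces(BoundaryTag.VESSEL)
    far = mesh.boundary_faces(BoundaryTag.FAR)
    s_in = np.zeros(mesh.n_faces)
    s_in[vessel] = params.s0

    def bolus_face_flux(s):
        """Volumetric bolus flux per face (m^3/s per unit area) at s."""
        s_up = _upwind_saturation(mesh, vt, s, params.s0, 0.0)
        f_up, _ = fractional_flow(s_up, params)
        flux = f_up * vt
        flux[i] += -TD / A_f[i] * (s[nbr[i]] - s[own[i]])
        return flux

    def residual(s):
        flux = bolus_face_flux(s)
        r = params.phi * V / dt * (s - s_old) + V * react * s
        np.add.at(r, own, A_f * flux)
        np.add.at(r, nbr[i], -(A_f[i] * flux[i]))
        return r

    def jacobian(s):
        rows = [np.arange(n)]
        cols = [np.arange(n)]
        vals = [np.full(n, params.phi * V / dt + V * react)]
        # diffusion part (coefficient lagged, linear in s)
        rows += [own[i], own[i], nbr[i], nbr[i]]
        cols += [own[i], nbr[i], nbr[i], own[i]]
        vals += [TD, -TD, TD, -TD]
        # advective part: d(f_o(s_up) vt)/ds_up, upwind cell only
        up_is_owner = vt > 0
        # interior faces
        fo_prime = fractional_flow(s, params)[1]
        ii = i[up_is_owner[i]]
        coef = A_f[ii] * vt[ii] * fo_prime[own[ii]]
        rows += [own[ii], nbr[ii]]
        cols += [own[ii], own[ii]]
        vals += [coef, -coef]
        jj = i[vt[i] < 0]
        coef = A_f[jj] * vt[jj] * fo_prime[nbr[jj]]
        rows += [own[jj], nbr[jj]]
        cols += [nbr[jj], nbr[jj]]
        vals += [coef, -coef]
        # boundary outflow faces (inflow faces have fixed composition)
        for bf in (vessel, far):
            f = bf[vt[bf] > 0]
            coef = A_f[f] * vt[f] * fo_prime[own[f]]
            rows.append(own[f])
            cols.append(own[f])
            vals.append(coef)
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        ).tocsr()

    s = s_old.copy()
    r = residual(s)
    scale = params.phi * V / dt * max(float(np.abs(s_old).max()), 1.0)
    r_norm = np.linalg.norm(r)
    converged = r_norm < NEWTON_ATOL * scale * np.sqrt(n)
    for it in range(NEWTON_MAXIT):
        if converged:
            break
        J = jacobian(s)
        ds = _linalg.solve(J, -r, x0=np.zeros(n))
        if not np.all(np.isfinite(ds)):
            raise TimeStepError("saturation Newton step non-finite")
        step = 1.0
        for _ in range(8):  # backtracking line search
            s_try = s + step * ds
            r_try = residual(s_try)
            if np.linalg.norm(r_try) < r_norm:
                break
            step *= 0.5
        s, r = s_try, r_try
        r_new = np.linalg.norm(r)
        converged = (
            r_new < NEWTON_ATOL * scale * np.sqrt(n)
            or r_new < NEWTON_RTOL * r_norm
            or r_new < 1e-14 * scale * np.sqrt(n) + 1e-300
        )
        r_norm = r_new
    else:
        if not converged:
            raise TimeStepError(
                f"saturation Newton failed: residual {r_norm:.2e} after "
                f"{NEWTON_MAXIT} iterations"
            )

    # clean up round-off excursions only (the scheme itself is bounded)
    s = np.clip(s, 0.0, 1.0)

    flux = bolus_face_flux(s)
    bnd = np.flatnonzero(~mesh.interior)
    boundary_influx = -float((A_f[bnd] * flux[bnd]).sum())
    reacted_rate = float(
        (params.gamma * params.rho_dcacl * params.epsilon * params.phi
         * s * V).sum()
    )
    diagnostics = {
        "boundary_bolus_volume_rate": boundary_influx,
        "reacted_mass_rate": reacted_rate,
        "residual": float(r_norm),
        "newton_iterations": it if converged else NEWTON_MAXIT,
    }
    return s, diagnostics
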