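"""Mixture temperature transport: porous convection, diffusion, reaction heat.

All constituents (tissue matrix, blood, bolus) are assumed in local thermal
equilibrium, so a single mixture temperature ``u`` (°C) is advanced with
volume-fraction-averaged thermal conductivity ``k = sum(phi_i * k_i)`` and
thermal inertia ``rho*c = sum(phi_i * rho_i * c_i)``. Convection carries
heat with the superficial phase fluxes weighted by each phase's volumetric
heat capacity; the exothermic hydrolysis of the bolus provides the
volumetric heat source.

Boundary conditions: zero temperature gradient on the far boundary; on the
vessel interface during injection a Robin inflow condition ties the
conductive flux to the mismatch between the boundary temperature and the
upstream hydrolysis temperature ``u0``, scaled by the inflow Darcy flux —
at strong inflow the boundary temperature approaches ``u0``. After the
delivery window the vessel faces are insulated.

Discretization: backward Euler in time; two-point flux with harmonic-mean
conductivity for diffusion; first-order upwinding of the non-conservative
convection term (monotone, so the discrete solution observes a maximum
principle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .chemistry import ParameterSet, heat_source
from .geometry import BoundaryTag, StructuredMesh
from .twophase_flow import FlowState, TimeStepError
from . import _linalg

__all__ = ["ThermalState", "mixture_properties", "advance_temperature"]


@dataclass
class ThermalState:
    """Temperature and mixture thermal fields at one time level.

    u : mixture temperature (°C) per cell.
    k_mix : volume-fraction-averaged conductivity (W/m/K) per cell.
    rhoc_mix : volume-fraction-averaged thermal inertia (J/m^3/K) per cell.
    r_total : total reaction heat source (W/m^3) per cell.
    """

    u: np.ndarray
    k_mix: np.ndarray
    rhoc_mix: np.ndarray
    r_total: np.ndarray


def mixture_properties(s_bolus: np.ndarray | float, params: ParameterSet):
    """Volume-fraction-averaged conductivity and thermal inertia.

    ``k = (1-phi) k_tissue + phi (s_blood k_blood + s_bolus k_bolus)`` and
    analogously ``rho*c``; both are convex combinations of the constituent
    values.
    """
    s_o = np.asarray(s_bolus, dtype=float)
    s_b = 1.0 - s_o
    phi = params.phi
    k_mix = (
        (1.0 - phi) * params.k_tissue
        + phi * (s_b * params.k_blood + s_o * params.k_bolus)
    )
    rhoc = (
        (1.0 - phi) * params.rho_tissue * params.c_tissue
        + phi * (
            s_b * params.rho_blood * params.c_blood
            + s_o * params.rho_bolus * params.c_bolus
        )
    )
    return k_mix, rhoc


def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def advance_temperature(
    u: np.ndarray,
    flow: FlowState,
    mesh: StructuredMesh,
    params: ParameterSet,
    bc,
    dt: float,
    t_new: float | None = None,
):
    """One backward-Euler step of the mixture temperature equation.

    ``rho*c du/dt + (rho_b c_b v_blood + rho_o c_o v_bolus) . grad(u)
    = div(k grad u) + r`` with the reaction heat source evaluated at the
    current bolus saturation (end-of-step value under operator splitting).

    Parameters
    ----------
    u : temperature field at the old time level (°C).
    flow : flow state providing saturations and face velocities.
    bc : injection schedule (``None`` disables the vessel inflow condition).
    t_new : time at the end of the step, used to decide whether the
        injection is active; defaults to "active" whenever ``bc`` is given
        and reports active at any time.

    Returns ``(u_new, ThermalState, diagnostics)``; diagnostics carry the
    reaction heat deposited this step (J), the boundary heat inflow (J) and
    the stepwise energy-balance residual.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = mesh.n_cells
    V = mesh.cell_volume
    s_o = flow.s_bolus
    k_mix, rhoc = mixture_properties(s_o, params)
    r = heat_source(s_o, params)

    diag = rhoc * V / dt
    rhs = rhoc * V / dt * u + V * r

    rows, cols, vals = [np.arange(n)], [np.arange(n)], [diag.copy()]

    own = mesh.face_owner
    nbr = mesh.face_neighbor
    A_f = mesh.face_area
    i = np.flatnonzero(mesh.interior)

    # diffusion, interior: -div(k grad u)
    Tk = _harmonic(k_mix[own[i]], k_mix[nbr[i]]) * A_f[i] / mesh.face_dist[i]
    rows += [own[i], own[i], nbr[i], nbr[i]]
    cols += [own[i], nbr[i], nbr[i], own[i]]
    vals += [Tk, -Tk, Tk, -Tk]

    # convection coefficient: volumetric heat-capacity-weighted face flux
    c_f = (
        params.rho_blood * params.c_blood * flow.v_blood
        + params.rho_bolus * params.c_bolus * flow.v_bolus
    )

    # interior upwind, non-conservative form: only inflow faces contribute,
    # bringing the upstream cell temperature
    ci, Ai = c_f[i], A_f[i]
    neg = ci < 0  # inflow into owner from neighbor
    f = i[neg]
    coef = A_f[f] * c_f[f]  # negative
    rows += [own[f], own[f]]
    cols += [nbr[f], own[f]]
    vals += [coef, -coef]
    pos = ci > 0  # inflow into neighbor from owner
    f = i[pos]
    coef = -A_f[f] * c_f[f]  # negative from neighbor's perspective
    rows += [nbr[f], nbr[f]]
    cols += [own[f], nbr[f]]
    vals += [coef, -coef]

    # vessel inflow: Robin condition blending boundary temperature toward u0
    injecting = bc is not None and (t_new is None or bc.active(t_new))
    robin_faces = np.empty(0, dtype=int)
    robin_coef = np.empty(0)
    u0 = None
    if injecting:
        u0 = bc.u0 if bc.u0 is not None else params.upstream_temp
        vf = mesh.boundary_faces(BoundaryTag.VESSEL)
        q_n = params.phi * (flow.v_blood[vf] + flow.v_bolus[vf])
        f = vf[q_n < 0]
        if len(f):
            qn = -q_n[q_n < 0]  # positive inflow magnitude
            kf = k_mix[own[f]]
            d = mesh.face_dist[f]
            if params.alpha is not None:
                alpha = np.full(len(f), params.alpha)
            else:
                vmag = np.abs(flow.v_blood[f] + flow.v_bolus[f])
                alpha = kf / (
                    params.rho_blood * params.c_blood * np.maximum(vmag, 1e-12)
                )
            # Robin closure for the face temperature:
            # u_face = omega*u0 + (1-omega)*u_cell
            omega = qn / (alpha / d + qn)
            # advective inflow at u_face plus conduction through the half cell
            robin_faces = f
            robin_coef = A_f[f] * (np.abs(c_f[f]) + kf / d) * omega
            rows.append(own[f])
            cols.append(own[f])
            vals.append(robin_coef)
            np.add.at(rhs, own[f], robin_coef * u0)

    # FAR faces: zero-gradient (no diffusive flux); advective outflow leaves
    # with the cell temperature, which contributes nothing in the
    # non-conservative upwind form. Inactive vessel faces are insulated.

    M = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    u_new = _linalg.solve(M, rhs, x0=u)
    if not np.all(np.isfinite(u_new)):
        raise TimeStepError("temperature solve produced non-finite values")
    res = np.linalg.norm(M @ u_new - rhs) / max(np.linalg.norm(rhs), 1.0)
    if res > 1e-8:
        raise TimeStepError(f"temperature residual {res:.2e} above tolerance")

    source_heat = float((V * r).sum()) * dt
    # boundary heat inflow: Robin terms evaluated at the new solution
    boundary_heat = 0.0
    if len(robin_faces):
        boundary_heat = float(
            (robin_coef * (u0 - u_new[own[robin_faces]])).sum()
        ) * dt

    state = ThermalState(u=u_new, k_mix=k_mix, rhoc_mix=rhoc, r_total=r)
    diagnostics = {
        "source_heat": source_heat,
        "boundary_heat": boundary_heat,
        "residual": float(res),
    }
    return u_new, state, diagnostics
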