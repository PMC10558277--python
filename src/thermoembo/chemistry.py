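"""Hydrolysis kinetics, inter-phase mass exchange and reaction heating.

Dichloroacetyl chloride (DCACl) delivered in an oily bolus hydrolyzes with
tissue water to dichloroacetic acid and HCl; secondary neutralization
reactions with latent tissue buffers follow effectively instantaneously.
The oil delays hydrolysis, giving first-order escape kinetics with rate
constant ``gamma`` (1/s). The combined heat of the primary and secondary
reactions is additive, ``h_total = h_dca + h_salt``.

The reaction converts bolus mass into blood mass at volumetric rate
``gamma * rho_dcacl * epsilon * phi * s_bolus`` (kg/m^3/s) and releases
heat at ``h_total`` per mole of DCACl consumed. The module also provides
the calorimetric upstream temperature (the maximum temperature complete
hydrolysis can produce in a reference tissue mass, used as the inflow
temperature at the vessel interface) and a first-order kinetics fit
``u(t) = u_ss * (1 - exp(-gamma*t))`` for estimating ``gamma`` from
measured time–temperature curves.

All quantities are SI except temperature, which is handled in degrees
Celsius throughout: the model is linear in temperature, so the offset to
kelvin cancels everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

__all__ = [
    "ParameterSet",
    "KineticsFitResult",
    "ParameterError",
    "FitError",
    "combined_heat",
    "bolus_mass_sink",
    "heat_source",
    "upstream_temperature",
    "fit_hydrolysis_rate",
    "dcacl_volume_fraction",
]

ATM = 101_325.0  # Pa


class ParameterError(ValueError):
    """Raised for physically inconsistent model parameters."""


class FitError(RuntimeError):
    """Raised when the kinetics fit fails to converge; carries last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


def combined_heat(h_dca: float, h_salt: float) -> float:
    """Combined heat of reaction (J/mol): hydrolysis plus secondary
    neutralization heats, which are additive."""
    if not (np.isfinite(h_dca) and np.isfinite(h_salt)):
        raise ParameterError("reaction heats must be finite")
    return h_dca + h_salt


def dcacl_volume_fraction(
    concentration_mol_per_l: float, w_dcacl: float, rho_dcacl: float
) -> float:
    """Volume fraction of DCACl within the bolus from its molar concentration.

    ``epsilon = c [mol/m^3] * W [kg/mol] / rho [kg/m^3]``; a 2 mol/L
    solution of DCACl (W = 0.147 kg/mol, rho = 1532 kg/m^3) gives
    epsilon ≈ 0.192.
    """
    if concentration_mol_per_l < 0 or w_dcacl <= 0 or rho_dcacl <= 0:
        raise ParameterError("concentration must be >=0; W and rho positive")
    eps = concentration_mol_per_l * 1e3 * w_dcacl / rho_dcacl
    if eps > 1.0 + 1e-12:
        raise ParameterError(
            f"volume fraction {eps:.4f} > 1: concentration exceeds pure DCACl"
        )
    return min(eps, 1.0)


@dataclass
class ParameterSet:
    """Physical constants and delivery settings for a thermoembolization run.

    Defaults describe a 2 mol/L DCACl-in-oil bolus injected at 1.16 atm into
    soft tissue of porosity 0.05 at ambient 21 °C. Tissue thermal
    conductivity and density are literature-typical soft-tissue values
    (the tissue is a fixed solid matrix, so it has no viscosity or
    permeability of its own; the permeability below is the soft-rock value
    used for both pore fluids).

    Parameters (SI, temperatures in °C):

    phi : porosity, void fraction of the tissue.
    epsilon : DCACl volume fraction within the bolus.
    gamma : first-order hydrolysis rate constant (1/s).
    h_dca, h_salt, h_total : hydrolysis, secondary, and combined heats of
        reaction (J/mol); ``h_total`` must equal their sum.
    rho_dcacl, w_dcacl : DCACl density (kg/m^3) and molar mass (kg/mol).
    *_tissue / *_blood / *_bolus : per-constituent density rho (kg/m^3),
        specific heat c (J/kg/K), conductivity k (W/m/K); blood and bolus
        additionally viscosity mu (Pa·s) and permeability kappa (m^2).
    pd : capillary displacement pressure (Pa).
    p_injection, p0 : injection and far-field (atmospheric) pressure (Pa).
    u_init : initial/ambient temperature (°C).
    u0 : upstream (maximum hydrolysis) temperature (°C); if None, computed
        calorimetrically from n_dcacl and m_tissue.
    s0 : inflow bolus saturation at the vessel interface.
    alpha : Robin coefficient for the temperature inflow condition (m);
        None selects the per-face default k/(rho_blood*c_blood*|v|), which
        drives the boundary temperature to u0 at strong inflow.
    n_dcacl, m_tissue : injected DCACl moles and reference tissue mass (kg)
        for the calorimetric upstream temperature.
    """

    phi: float = 0.05
    epsilon: float = dcacl_volume_fraction(2.0, 0.147, 1532.0)
    gamma: float = 2.33e-3
    h_dca: float = 93e3
    h_salt: float = 45e3
    h_total: float = 138e3
    rho_dcacl: float = 1532.0
    w_dcacl: float = 0.147

    rho_tissue: float = 1050.0
    c_tissue: float = 3600.0
    k_tissue: float = 0.5

    rho_blood: float = 1045.0
    c_blood: float = 3600.0
    k_blood: float = 0.53
    mu_blood: float = 8.90e-4
    kappa_blood: float = 5e-12

    rho_bolus: float = 1280.0
    c_bolus: float = 1970.0
    k_bolus: float = 0.15
    mu_bolus: float = 0.70e-3
    kappa_bolus: float = 5e-12

    pd: float = 0.074 * ATM
    p_injection: float = 1.16 * ATM
    p0: float = ATM
    u_init: float = 21.0
    u0: float | None = None
    s0: float = 1.0
    alpha: float | None = None
    n_dcacl: float = 2e-3
    m_tissue: float = 1e-3

    def __post_init__(self) -> None:
        positive = {
            "rho_dcacl": self.rho_dcacl, "w_dcacl": self.w_dcacl,
            "rho_tissue": self.rho_tissue, "c_tissue": self.c_tissue,
            "k_tissue": self.k_tissue, "rho_blood": self.rho_blood,
            "c_blood": self.c_blood, "k_blood": self.k_blood,
            "mu_blood": self.mu_blood, "kappa_blood": self.kappa_blood,
            "rho_bolus": self.rho_bolus, "c_bolus": self.c_bolus,
            "k_bolus": self.k_bolus, "mu_bolus": self.mu_bolus,
            "kappa_bolus": self.kappa_bolus, "m_tissue": self.m_tissue,
        }
        for name, val in positive.items():
            if not val > 0:
                raise ParameterError(f"{name} must be strictly positive, got {val}")
        if not 0 < self.phi < 1:
            raise ParameterError(f"porosity must lie in (0,1), got {self.phi}")
        if not 0 <= self.epsilon <= 1:
            raise ParameterError(f"epsilon must lie in [0,1], got {self.epsilon}")
        if self.gamma < 0:
            raise ParameterError(f"gamma must be >= 0, got {self.gamma}")
        if not 0 <= self.s0 <= 1:
            raise ParameterError(f"s0 must lie in [0,1], got {self.s0}")
        if not np.isclose(self.h_total, self.h_dca + self.h_salt, rtol=1e-9):
            raise ParameterError(
                f"h_total={self.h_total} must equal h_dca+h_salt="
                f"{self.h_dca + self.h_salt}"
            )

    @property
    def upstream_temp(self) -> float:
        """u0 if set, otherwise the calorimetric upstream temperature."""
        if self.u0 is not None:
            return self.u0
        return upstream_temperature(self)

    def with_(self, **kwargs) -> "ParameterSet":
        """Copy with selected fields replaced (re-validated)."""
        return replace(self, **kwargs)


def bolus_mass_sink(s_bolus: np.ndarray | float, params: ParameterSet) -> np.ndarray:
    """Volumetric bolus mass sink from hydrolysis (kg/m^3/s), <= 0.

    ``q_bolus = -gamma * rho_dcacl * epsilon * phi * s_bolus``; the blood
    source is its negation (mass conversion between constituents).
    """
    s = np.asarray(s_bolus, dtype=float)
    return -params.gamma * params.rho_dcacl * params.epsilon * params.phi * s


def heat_source(s_bolus: np.ndarray | float, params: ParameterSet) -> np.ndarray:
    """Volumetric reaction heat source (W/m^3), >= 0.

    ``r = h_total * gamma * rho_dcacl * epsilon * phi * s_bolus / w_dcacl``:
    the molar consumption rate of DCACl times the combined heat of reaction.
    """
    if params.w_dcacl == 0:
        raise ParameterError("w_dcacl must be nonzero")
    s = np.asarray(s_bolus, dtype=float)
    return (
        params.h_total * params.gamma * params.rho_dcacl
        * params.epsilon * params.phi * s / params.w_dcacl
    )


def upstream_temperature(params: ParameterSet) -> float:
    """Maximum temperature (°C) from complete hydrolysis in ``m_tissue``.

    ``u0 = u_init + h_total * n_dcacl / (m_tissue * c_tissue)``.
    """
    if params.m_tissue <= 0 or params.c_tissue <= 0:
        raise ParameterError("m_tissue and c_tissue must be positive")
    return params.u_init + params.h_total * params.n_dcacl / (
        params.m_tissue * params.c_tissue
    )


@dataclass
class KineticsFitResult:
    """Fitted first-order rise parameters.

    uss : steady-state temperature rise above baseline (°C).
    gamma_hat : fitted rate constant (1/s), >= 0.
    residual_norm : root-mean-square fit residual (°C).
    """

    uss: float
    gamma_hat: float
    residual_norm: float


def fit_hydrolysis_rate(
    times: np.ndarray,
    temps: np.ndarray,
    baseline: float = 0.0,
    max_iter: int = 500,
) -> KineticsFitResult:
    """Fit ``u(t) = u_ss * (1 - exp(-gamma*t))`` to a temperature rise curve.

    Parameters
    ----------
    times : sample times (s), strictly increasing, at least 3 samples.
    temps : temperatures (°C); ``baseline`` is subtracted before fitting.
    baseline : ambient temperature to subtract (pass 0 for rise data).

    Returns
    -------
    KineticsFitResult with nonnegative ``gamma_hat`` and the RMS residual.

    Initialization: u_ss from the maximum observed rise, gamma from the
    reciprocal half-rise time; bounded trust-region least squares keeps
    both parameters nonnegative.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(temps, dtype=float) - baseline
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and temps must be equal-length 1-D arrays")
    if len(t) < 3:
        raise ValueError("at least 3 samples are required")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")

    uss0 = max(float(y.max()), 1e-12)
    half = np.flatnonzero(y >= 0.5 * uss0)
    t_half = t[half[0]] if len(half) and t[half[0]] > 0 else max(t[-1] / 2, 1e-12)
    x0 = np.array([uss0, 1.0 / t_half])

    def model(p, tt):
        return p[0] * (1.0 - np.exp(-p[1] * tt))

    res = optimize.least_squares(
        lambda p: model(p, t) - y,
        x0,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        max_nfev=max_iter * len(x0),
    )
    if not res.success:
        raise FitError(f"kinetics fit failed: {res.message}", last_iterate=res.x)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return KineticsFitResult(uss=float(res.x[0]), gamma_hat=float(res.x[1]),
                             residual_norm=rms)
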