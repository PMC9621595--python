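"""Algebraic and differential relations of the glucose-insulin model.

All functions here are pure evaluations (no integration).  The model couples
a fast component -- glucose and insulin mass balances between the two
flow-connected compartments -- with a slow component describing hepatic
insulin-resistance development (driven by the integral of excess glucose)
and beta-cell adaptation (a bell-shaped net growth rate in long-term
average glucose, after Topp-type beta-cell mass dynamics).
"""

from __future__ import annotations

import math

import numpy as np

from .config import ChipConfig, ModelParameters, SystemState, STATE_FIELDS

__all__ = [
    "sigma_of_t",
    "insulin_sensitivity",
    "beta_net_growth_rate",
    "beta_steady_states",
    "insulin_secretion_flux",
    "hepatic_glucose_uptake_flux",
    "hepatic_insulin_clearance_flux",
    "rhs",
]


def sigma_of_t(sigma_max: float, alpha: float, t: float) -> float:
    """Beta-cell secretion capacity at culture time ``t``: a sigmoidal decay
    ``sigma_max * (1 - t^2 / (alpha + t^2))``.

    ``t`` is time since co-culture start (h), shared across regimes; the
    shape parameter ``alpha`` (h^2) sets the half-decay time ``sqrt(alpha)``.
    For very large ``alpha`` the decay is negligible over a culture.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    if alpha == 0.0 and t == 0.0:
        return sigma_max
    return sigma_max * (1.0 - t * t / (alpha + t * t))


def insulin_sensitivity(S_I0: float, Imax_Si: float, EC50_Si: float,
                        G_int: float) -> float:
    """Hepatic insulin sensitivity after cumulative hyperglycemic exposure.

    ``S_I0 * (1 - Imax_Si * G_int / (EC50_Si + G_int))``: non-increasing in
    the excess-glucose integral ``G_int`` and bounded below by
    ``S_I0 * (1 - Imax_Si)``.  The 0/0 case (``EC50_Si == G_int == 0``) is
    defined as no reduction.
    """
    if G_int < 0:
        raise ValueError("G_int must be nonnegative")
    if EC50_Si + G_int == 0.0:
        return S_I0
    return S_I0 * (1.0 - Imax_Si * G_int / (EC50_Si + G_int))


def beta_net_growth_rate(params: ModelParameters, G_slow: float) -> float:
    """Specific net growth rate of beta-cell volume (1/h) at long-term
    average glucose ``G_slow``: ``k_v * (-d0 + r1*G - r2*G^2)``.

    Negative at zero glucose, positive strictly between the two roots of the
    quadratic (5.56 and 13.89 mM at the default constants) and maximal at
    ``r1 / (2 r2)``.
    """
    if G_slow < 0:
        raise ValueError("G_slow must be nonnegative")
    return params.k_v * (-params.d0 + params.r1 * G_slow
                         - params.r2 * G_slow**2)


def beta_steady_states(params: ModelParameters) -> tuple[float, float]:
    """The two glucose concentrations (mmol/L) at which the net beta-cell
    growth rate vanishes, from the quadratic formula."""
    disc = params.r1**2 - 4.0 * params.r2 * params.d0
    if disc < 0:
        raise ValueError("no real steady states: r1^2 < 4*r2*d0")
    root = math.sqrt(disc)
    lo = (params.r1 - root) / (2.0 * params.r2)
    hi = (params.r1 + root) / (2.0 * params.r2)
    return lo, hi


def insulin_secretion_flux(V_beta: float, sigma: float, EC50_I: float,
                           G_pancreas: float) -> float:
    """Islet insulin secretion flux (mIU/h): a Hill function of pancreas
    glucose with coefficient 2, ``V_beta * sigma * G^2 / (EC50_I^2 + G^2)``."""
    for name, v in (("V_beta", V_beta), ("sigma", sigma),
                    ("EC50_I", EC50_I), ("G_pancreas", G_pancreas)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    denom = EC50_I**2 + G_pancreas**2
    if denom == 0.0:
        return 0.0
    return V_beta * sigma * G_pancreas**2 / denom


def hepatic_glucose_uptake_flux(config: ChipConfig, E_G0: float, S_I: float,
                                G_liver: float, I_liver: float) -> float:
    """Glucose uptake by the hepatic spheroids (mmol/h):
    ``V_hepaRG * (E_G0 + S_I * I_liver) * G_liver``.

    Insulin enhances the insulin-independent disposal rate linearly through
    the sensitivity ``S_I``.
    """
    if G_liver < 0 or I_liver < 0:
        raise ValueError("concentrations must be nonnegative")
    return config.V_hepaRG * (E_G0 + S_I * I_liver) * G_liver


def hepatic_insulin_clearance_flux(config: ChipConfig, CL_I_spheroids: float,
                                   I_liver: float) -> float:
    """Insulin elimination by the hepatic spheroids (mIU/h):
    ``CL_I_spheroids * V_hepaRG * I_liver``.

    The implied whole-medium first-order elimination rate is
    ``CL * V_hepaRG / V_m_liver`` (see :mod:`isletchip.translate`).
    """
    if I_liver < 0:
        raise ValueError("I_liver must be nonnegative")
    return CL_I_spheroids * config.V_hepaRG * I_liver


def rhs(state: SystemState, params: ModelParameters,
        config: ChipConfig | None = None) -> np.ndarray:
    """Time derivative of the dynamic state vector (order ``STATE_FIELDS``).

    Assembles the mass balances: glucose dosing is handled as discrete
    events elsewhere, so the liver glucose balance holds endogenous
    production (zero by default), hepatic uptake and flow exchange; the
    pancreas glucose balance is flow-only; insulin is secreted into the
    pancreas medium and eliminated from the liver medium; the slow variables
    integrate excess liver glucose, relax pancreas glucose toward its
    long-term average, and grow/shrink the beta-cell volume.
    """
    state.validate()
    if config is None:
        config = ChipConfig()
    V_ml = state.V_m_liver_now
    V_mp = state.V_m_pancreas_now
    G_l, G_p = state.NG_liver / V_ml, state.NG_pancreas / V_mp
    I_l, I_p = state.NI_liver / V_ml, state.NI_pancreas / V_mp

    S_I = insulin_sensitivity(params.S_I0, params.Imax_Si, params.EC50_Si,
                              state.G_int)
    sigma = sigma_of_t(params.sigma_max, params.alpha, state.t)

    dNG_liver = (config.V_hepaRG * params.EGP
                 - hepatic_glucose_uptake_flux(config, params.E_G0, S_I, G_l, I_l)
                 + config.Q * (G_p - G_l))
    dNG_pancreas = config.Q * (G_l - G_p)
    dNI_pancreas = (insulin_secretion_flux(state.V_beta, sigma,
                                           params.EC50_I, G_p)
                    + config.Q * (I_l - I_p))
    dNI_liver = (-hepatic_insulin_clearance_flux(config, params.CL_I_spheroids, I_l)
                 + config.Q * (I_p - I_l))
    dG_int = max(0.0, G_l - params.G_normo)
    dG_slow = (G_p - state.G_slow) / params.tau_slow
    dV_beta = beta_net_growth_rate(params, state.G_slow) * state.V_beta

    return np.array([dNG_liver, dNG_pancreas, dNI_liver, dNI_pancreas,
                     dG_int, dG_slow, dV_beta])
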