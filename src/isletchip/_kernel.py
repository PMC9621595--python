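"""Compiled numerical kernels.

The right-hand side and a fixed-step classical RK4 integrator are compiled
with numba so that calibration (tens of thousands of full-protocol
simulations) stays fast.  The kernels operate on a flat float64 parameter
vector; :func:`pack_params` builds it from the dataclass types.  Agreement
with the pure-Python :func:`isletchip.model.rhs` and with scipy's adaptive
integration is asserted in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .config import ChipConfig, ModelParameters

# parameter-vector layout (kept in one place; kernels index by these names)
(P_EG0, P_CL, P_SI0, P_IMAX, P_EC50SI, P_GNORMO, P_SIGMAX, P_ALPHA, P_EC50I,
 P_D0, P_R1, P_R2, P_KV, P_TAUSLOW, P_EGP, P_VHEP, P_Q) = range(17)
N_P = 17


def pack_params(params: ModelParameters, config: ChipConfig) -> np.ndarray:
    p = np.empty(N_P)
    p[P_EG0] = params.E_G0
    p[P_CL] = params.CL_I_spheroids
    p[P_SI0] = params.S_I0
    p[P_IMAX] = params.Imax_Si
    p[P_EC50SI] = params.EC50_Si
    p[P_GNORMO] = params.G_normo
    p[P_SIGMAX] = params.sigma_max
    p[P_ALPHA] = params.alpha
    p[P_EC50I] = params.EC50_I
    p[P_D0] = params.d0
    p[P_R1] = params.r1
    p[P_R2] = params.r2
    p[P_KV] = params.k_v
    p[P_TAUSLOW] = params.tau_slow
    p[P_EGP] = params.EGP
    p[P_VHEP] = config.V_hepaRG
    p[P_Q] = config.Q
    return p


@njit(cache=True)
def rhs_kernel(t, y, p, vml, vmp, out):
    """Derivative of y = [NG_l, NG_p, NI_l, NI_p, G_int, G_slow, V_beta]."""
    G_l = y[0] / vml
    G_p = y[1] / vmp
    I_l = y[2] / vml
    I_p = y[3] / vmp

    denom_si = p[P_EC50SI] + y[4]
    if denom_si > 0.0:
        S_I = p[P_SI0] * (1.0 - p[P_IMAX] * y[4] / denom_si)
    else:
        S_I = p[P_SI0]
    denom_sig = p[P_ALPHA] + t * t
    if denom_sig > 0.0:
        sigma = p[P_SIGMAX] * (1.0 - t * t / denom_sig)
    else:
        sigma = p[P_SIGMAX]

    uptake = p[P_VHEP] * (p[P_EG0] + S_I * I_l) * G_l
    out[0] = p[P_VHEP] * p[P_EGP] - uptake + p[P_Q] * (G_p - G_l)
    out[1] = p[P_Q] * (G_l - G_p)

    denom_hill = p[P_EC50I] * p[P_EC50I] + G_p * G_p
    if denom_hill > 0.0:
        secretion = y[6] * sigma * G_p * G_p / denom_hill
    else:
        secretion = 0.0
    out[3] = secretion + p[P_Q] * (I_l - I_p)
    out[2] = -p[P_CL] * p[P_VHEP] * I_l + p[P_Q] * (I_p - I_l)

    excess = G_l - p[P_GNORMO]
    out[4] = excess if excess > 0.0 else 0.0
    out[5] = (G_p - y[5]) / p[P_TAUSLOW]
    out[6] = p[P_KV] * (-p[P_D0] + p[P_R1] * y[5] - p[P_R2] * y[5] * y[5]) * y[6]


@njit(cache=True)
def _rk4_step(t, y, h, p, vml, vmp, k1, k2, k3, k4, tmp):
    rhs_kernel(t, y, p, vml, vmp, k1)
    for i in range(7):
        tmp[i] = y[i] + 0.5 * h * k1[i]
    rhs_kernel(t + 0.5 * h, tmp, p, vml, vmp, k2)
    for i in range(7):
        tmp[i] = y[i] + 0.5 * h * k2[i]
    rhs_kernel(t + 0.5 * h, tmp, p, vml, vmp, k3)
    for i in range(7):
        tmp[i] = y[i] + h * k3[i]
    rhs_kernel(t + h, tmp, p, vml, vmp, k4)
    for i in range(7):
        y[i] = y[i] + h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
        # amounts and slow variables are physically nonnegative; clip the
        # tiny negative excursions of the explicit step near zero
        if y[i] < 0.0 and y[i] > -1e-12:
            y[i] = 0.0


@njit(cache=True)
def integrate_segment(y, t0, t1, dt, p, vml, vmp, t_out, out):
    """Advance ``y`` in place from t0 to t1 with RK4 steps of size <= dt.

    States at the (sorted, within [t0, t1]) times ``t_out`` are written into
    ``out`` (shape (len(t_out), 7)).  Returns the final time.
    """
    k1 = np.empty(7)
    k2 = np.empty(7)
    k3 = np.empty(7)
    k4 = np.empty(7)
    tmp = np.empty(7)
    t = t0
    j = 0
    n_out = t_out.shape[0]
    while j < n_out and t_out[j] <= t + 1e-12:
        for i in range(7):
            out[j, i] = y[i]
        j += 1
    while t < t1 - 1e-12:
        t_next = t1
        if j < n_out and t_out[j] < t_next:
            t_next = t_out[j]
        span = t_next - t
        n_steps = int(np.ceil(span / dt - 1e-12))
        if n_steps < 1:
            n_steps = 1
        h = span / n_steps
        for _ in range(n_steps):
            _rk4_step(t, y, h, p, vml, vmp, k1, k2, k3, k4, tmp)
            t += h
        t = t_next
        while j < n_out and t_out[j] <= t + 1e-12:
            for i in range(7):
                out[j, i] = y[i]
            j += 1
    return t
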