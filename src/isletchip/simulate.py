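"""Event-driven integration of the model over a culture protocol.

A protocol is a timeline of discrete events (media exchanges, sample
withdrawals) separated by smooth ODE segments.  Between events the system
is integrated either with scipy's adaptive RK45 at rtol 1e-8 (the default
contract) or with a compiled fixed-step RK4 used by the calibration hot
loop; both paths share the same compiled right-hand side.  Across events
the slow variables (G_int, G_slow, V_beta) are continuous; only medium
amounts and volumes jump.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from ._kernel import integrate_segment, pack_params, rhs_kernel
from .config import (ChipConfig, ModelParameters, OffsetParameters,
                     SystemState, STATE_FIELDS)
from .model import insulin_sensitivity, sigma_of_t, beta_net_growth_rate
from .protocol import (CultureProtocol, MediaExchangeEvent, SamplingEvent,
                       single_dose_protocol)

__all__ = [
    "Measurement",
    "Trajectory",
    "SimulationError",
    "apply_media_exchange",
    "apply_sampling",
    "simulate_protocol",
    "predict_with_dose_uncertainty",
    "DosePredictionBand",
]

# absolute floors per state component used for negative-excursion checks
_ATOL = np.array([1e-12, 1e-12, 1e-10, 1e-10, 1e-10, 1e-10, 1e-20])


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Measurement:
    """A single simulated measurement record."""

    time: float
    observable: str  # "glucose" | "insulin"
    compartment: str  # "pooled" | "liver" | "pancreas"
    value: float


@dataclass
class Trajectory:
    """Dense model trajectory with derived mechanistic variables.

    ``times`` may contain duplicate entries at event times: the first row
    holds the pre-event state, the second the post-event state, making the
    concentration jumps at media exchanges explicit.
    """

    times: np.ndarray
    states: np.ndarray  # (n, 7) in STATE_FIELDS order
    V_liver: np.ndarray
    V_pancreas: np.ndarray
    params: ModelParameters
    config: ChipConfig

    def column(self, name: str) -> np.ndarray:
        return self.states[:, STATE_FIELDS.index(name)]

    @property
    def G_liver(self) -> np.ndarray:
        return self.column("NG_liver") / self.V_liver

    @property
    def G_pancreas(self) -> np.ndarray:
        return self.column("NG_pancreas") / self.V_pancreas

    @property
    def I_liver(self) -> np.ndarray:
        return self.column("NI_liver") / self.V_liver

    @property
    def I_pancreas(self) -> np.ndarray:
        return self.column("NI_pancreas") / self.V_pancreas

    @property
    def G_pooled(self) -> np.ndarray:
        return 0.5 * (self.G_liver + self.G_pancreas)

    @property
    def I_pooled(self) -> np.ndarray:
        return 0.5 * (self.I_liver + self.I_pancreas)

    @property
    def G_int(self) -> np.ndarray:
        return self.column("G_int")

    @property
    def G_slow(self) -> np.ndarray:
        return self.column("G_slow")

    @property
    def V_beta(self) -> np.ndarray:
        return self.column("V_beta")

    @property
    def S_I(self) -> np.ndarray:
        p = self.params
        g = self.column("G_int")
        return np.array([insulin_sensitivity(p.S_I0, p.Imax_Si, p.EC50_Si, x)
                         for x in g])

    @property
    def sigma(self) -> np.ndarray:
        p = self.params
        return np.array([sigma_of_t(p.sigma_max, p.alpha, t)
                         for t in self.times])

    @property
    def beta_net_growth(self) -> np.ndarray:
        return np.array([beta_net_growth_rate(self.params, g)
                         for g in self.column("G_slow")])

    def state_at(self, index: int) -> SystemState:
        return SystemState.from_vector(self.times[index], self.states[index],
                                       self.V_liver[index],
                                       self.V_pancreas[index])

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (time, variable, compartment)."""
        blocks = []
        for var, comp, vals, units in [
            ("glucose", "liver", self.G_liver, "mmol/L"),
            ("glucose", "pancreas", self.G_pancreas, "mmol/L"),
            ("glucose", "pooled", self.G_pooled, "mmol/L"),
            ("insulin", "liver", self.I_liver, "mIU/L"),
            ("insulin", "pancreas", self.I_pancreas, "mIU/L"),
            ("insulin", "pooled", self.I_pooled, "mIU/L"),
            ("S_I", "-", self.S_I, "L/mIU/h"),
            ("sigma", "-", self.sigma, "mIU/L/h"),
            ("G_int", "-", self.column("G_int"), "mmol*h/L"),
            ("G_slow", "-", self.column("G_slow"), "mmol/L"),
            ("V_beta", "-", self.column("V_beta"), "L"),
        ]:
            blocks.append(pd.DataFrame({
                "time_h": self.times, "variable": var, "compartment": comp,
                "value": vals, "units": units}))
        return pd.concat(blocks, ignore_index=True)

    def value_at(self, attr: str, t: float) -> float:
        """Interpolated value of a derived series at time t."""
        return float(np.interp(t, self.times, getattr(self, attr)))


def apply_media_exchange(state: SystemState, event: MediaExchangeEvent,
                         config: ChipConfig) -> SystemState:
    """Replace both compartments' medium with fresh medium.

    Glucose is set to ``G_new + dG`` and insulin to ``I_new + dI`` (floored
    at zero) in both compartments; the medium volumes are reset to nominal.
    Slow variables are continuous across the event.
    """
    if event.time < state.t - 1e-9:
        raise ValueError("event time precedes current state time")
    G = event.G_new + event.dG
    if G < 0:
        raise ValueError("exchange glucose concentration G_new + dG < 0")
    I = max(0.0, event.I_new + event.dI)
    new = state.copy()
    new.t = event.time
    new.V_m_liver_now = config.V_m_liver
    new.V_m_pancreas_now = config.V_m_pancreas
    new.NG_liver = G * config.V_m_liver
    new.NG_pancreas = G * config.V_m_pancreas
    new.NI_liver = I * config.V_m_liver
    new.NI_pancreas = I * config.V_m_pancreas
    return new


def apply_sampling(state: SystemState, event: SamplingEvent,
                   config: ChipConfig, track_volumes: bool = True
                   ) -> tuple[SystemState, list[Measurement]]:
    """Withdraw medium from both compartments and emit measurements.

    Measurements are computed from the concentrations immediately before
    removal.  Removal leaves concentrations unchanged; with volume tracking
    on, amounts and volumes shrink proportionally.
    """
    v = event.volume_per_compartment
    if v > min(state.V_m_liver_now, state.V_m_pancreas_now) - 1e-12:
        raise ValueError("sample volume exceeds available medium")
    G_l, G_p = state.G_liver, state.G_pancreas
    I_l, I_p = state.I_liver, state.I_pancreas
    t = event.time
    if event.pooled:
        measurements = [
            Measurement(t, "glucose", "pooled", 0.5 * (G_l + G_p)),
            Measurement(t, "insulin", "pooled", 0.5 * (I_l + I_p)),
        ]
    else:
        measurements = [
            Measurement(t, "glucose", "liver", G_l),
            Measurement(t, "glucose", "pancreas", G_p),
            Measurement(t, "insulin", "liver", I_l),
            Measurement(t, "insulin", "pancreas", I_p),
        ]
    new = state.copy()
    new.t = t
    if track_volumes and v > 0:
        fl = (state.V_m_liver_now - v) / state.V_m_liver_now
        fp = (state.V_m_pancreas_now - v) / state.V_m_pancreas_now
        new.V_m_liver_now = state.V_m_liver_now - v
        new.V_m_pancreas_now = state.V_m_pancreas_now - v
        new.NG_liver *= fl
        new.NI_liver *= fl
        new.NG_pancreas *= fp
        new.NI_pancreas *= fp
    return new, measurements


def _effective_event(event, offsets: Optional[OffsetParameters]):
    """Apply run-time offsets to the tagged GTT exchanges."""
    if offsets is None or not isinstance(event, MediaExchangeEvent):
        return event
    if event.starts_gtt == "d1":
        return MediaExchangeEvent(event.time, event.G_new, event.I_new,
                                  offsets.dG_d1, offsets.dI_d1, "d1")
    if event.starts_gtt == "d13":
        return MediaExchangeEvent(event.time, event.G_new, event.I_new,
                                  offsets.dG_d13, offsets.dI_d13, "d13")
    return event


def _check_negative(y: np.ndarray, t: float) -> None:
    bad = y < -100.0 * _ATOL
    if bad.any():
        names = [STATE_FIELDS[i] for i in np.where(bad)[0]]
        raise SimulationError(
            f"negative state excursion in {names} at t = {t:.3f} h")
    np.clip(y, 0.0, None, out=y)


def _segment_adaptive(y, t0, t1, p, vml, vmp, t_out, rtol):
    def fun(t, yy):
        out = np.empty(7)
        rhs_kernel(t, yy, p, vml, vmp, out)
        return out

    if len(t_out) and t_out[-1] < t1 - 1e-12:
        raise AssertionError("output grid must end at the segment boundary")
    sol = solve_ivp(fun, (t0, t1), y, method="RK45", rtol=rtol, atol=_ATOL,
                    t_eval=t_out if len(t_out) else None, dense_output=False)
    if not sol.success:
        raise SimulationError(f"integrator failed near t = {sol.t[-1]:.3f} h: "
                              f"{sol.message}")
    y_end = sol.y[:, -1].copy()
    return (sol.y.T.copy() if len(t_out) else np.empty((0, 7))), y_end


def simulate_protocol(
    params: ModelParameters,
    offsets: Optional[OffsetParameters],
    config: ChipConfig,
    protocol: CultureProtocol,
    *,
    method: str = "adaptive",
    rtol: float = 1e-8,
    dt: float = 0.02,
    dense_dt: float = 1.0,
    track_volumes: bool = True,
    dose_shift: float = 0.0,
    record_trajectory: bool = True,
) -> tuple[Optional[Trajectory], list[Measurement]]:
    """Piecewise integration of the model over a protocol.

    The initial condition applies an implicit t = 0 exchange: both
    compartments filled at the regime's dose with zero insulin, G_int = 0,
    V_beta = V_beta0, and G_slow equal to the initial pancreas
    concentration (avoiding an artificial relaxation transient).

    Parameters
    ----------
    offsets : optional; when given, overrides the dG/dI carried by the
        protocol's tagged GTT exchanges, allowing one protocol object to be
        reused across calibration iterations.
    method : "adaptive" (RK45, ``rtol``) or "fixed" (compiled RK4, ``dt``).
    dose_shift : additive perturbation (mmol/L) applied to the glucose
        concentration of the initial fill and of every exchange; used for
        dose-uncertainty envelopes.
    record_trajectory : when False, only measurements are produced (the
        calibration hot path).
    """
    if method not in ("adaptive", "fixed"):
        raise ValueError(f"unknown method {method!r}")
    p = pack_params(params, config)
    G0 = max(0.0, protocol.regime.G_dose + dose_shift)
    vml, vmp = config.V_m_liver, config.V_m_pancreas
    y = np.array([G0 * vml, G0 * vmp, 0.0, 0.0, 0.0, G0, params.V_beta0])

    traj_t: list[float] = []
    traj_y: list[np.ndarray] = []
    traj_vl: list[float] = []
    traj_vp: list[float] = []

    def record(t, yy, a, b):
        traj_t.append(t)
        traj_y.append(yy.copy())
        traj_vl.append(a)
        traj_vp.append(b)

    measurements: list[Measurement] = []
    t_cur = 0.0
    boundaries = list(protocol.events)
    if not boundaries or boundaries[-1].time < protocol.duration:
        boundaries.append(None)  # sentinel: integrate to protocol.duration

    for event in boundaries:
        t_ev = protocol.duration if event is None else event.time
        if t_ev > t_cur + 1e-12:
            if record_trajectory:
                grid = np.arange(t_cur, t_ev, dense_dt)
                if len(grid) == 0 or grid[-1] < t_ev - 1e-12:
                    grid = np.append(grid, t_ev)
            else:
                grid = np.array([])
            if method == "fixed":
                out = np.empty((len(grid), 7))
                integrate_segment(y, t_cur, t_ev, dt, p, vml, vmp, grid, out)
                seg_states = out
            else:
                seg_states, y = _segment_adaptive(y, t_cur, t_ev, p, vml,
                                                  vmp, grid, rtol)
            _check_negative(y, t_ev)
            if record_trajectory:
                for tt, yy in zip(grid, seg_states):
                    record(tt, yy, vml, vmp)
            t_cur = t_ev
        if event is None:
            continue
        event = _effective_event(event, offsets)
        state = SystemState.from_vector(t_cur, y, vml, vmp)
        if isinstance(event, MediaExchangeEvent):
            ev = event
            if dose_shift != 0.0:
                ev = MediaExchangeEvent(ev.time,
                                        max(0.0, ev.G_new + dose_shift),
                                        ev.I_new, ev.dG, ev.dI, ev.starts_gtt)
            state = apply_media_exchange(state, ev, config)
        else:
            state, ms = apply_sampling(state, event, config, track_volumes)
            measurements.extend(ms)
        y = state.as_vector()
        vml, vmp = state.V_m_liver_now, state.V_m_pancreas_now
        if record_trajectory:
            record(t_cur, y, vml, vmp)

    trajectory = None
    if record_trajectory:
        trajectory = Trajectory(times=np.array(traj_t),
                                states=np.array(traj_y),
                                V_liver=np.array(traj_vl),
                                V_pancreas=np.array(traj_vp),
                                params=params, config=config)
    return trajectory, measurements


@dataclass
class DosePredictionBand:
    """Pointwise min/max envelope of trajectories over a dose-perturbation
    grid, plus the corresponding measurement-level band table."""

    times: np.ndarray
    nominal: dict
    lo: dict
    hi: dict
    measurement_table: pd.DataFrame


def predict_with_dose_uncertainty(
    params: ModelParameters,
    offsets: Optional[OffsetParameters],
    config: ChipConfig,
    protocol: CultureProtocol,
    dose_halfwidth: float,
    n_grid: int = 5,
    **sim_kwargs,
) -> DosePredictionBand:
    """Prediction envelope under glucose-dose uncertainty.

    The glucose concentration of every exchange (including the initial
    fill) is perturbed over a symmetric grid in [-h, +h]; the returned band
    is the pointwise min/max over the grid and always contains the nominal
    trajectory (the grid includes 0).
    """
    if dose_halfwidth < 0:
        raise ValueError("dose_halfwidth must be nonnegative")
    shifts = np.linspace(-dose_halfwidth, dose_halfwidth, max(2, n_grid))
    if not np.any(np.isclose(shifts, 0.0)):
        shifts = np.sort(np.append(shifts, 0.0))
    runs = []
    for s in shifts:
        traj, ms = simulate_protocol(params, offsets, config, protocol,
                                     dose_shift=float(s), **sim_kwargs)
        runs.append((s, traj, ms))
    nominal = next(r for r in runs if np.isclose(r[0], 0.0))
    times = nominal[1].times
    series = {"glucose": "G_pooled", "insulin": "I_pooled"}
    lo, hi, nom = {}, {}, {}
    for obs, attr in series.items():
        stack = np.vstack([getattr(traj, attr) for _, traj, _ in runs])
        lo[obs], hi[obs] = stack.min(axis=0), stack.max(axis=0)
        nom[obs] = getattr(nominal[1], attr)
    rows = []
    for m_nom in nominal[2]:
        vals = [m.value for _, _, ms in runs for m in ms
                if m.time == m_nom.time and m.observable == m_nom.observable
                and m.compartment == m_nom.compartment]
        rows.append(dict(time_h=m_nom.time, observable=m_nom.observable,
                         compartment=m_nom.compartment, lo=min(vals),
                         hi=max(vals), nominal=m_nom.value))
    return DosePredictionBand(times=times, nominal=nom, lo=lo, hi=hi,
                              measurement_table=pd.DataFrame(rows))
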