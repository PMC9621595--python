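"""Experiment-wise calibration: weighted cost, chi-square gate, annealing.

The calibration cost is the SEM-weighted sum of squared residuals over all
measured time points of all series,

    V(p) = sum_i sum_t (y_i(t) - yhat_i(t, p))^2 / SEM_i(t)^2,

compared against the 95% quantile of the chi-square distribution with
degrees of freedom equal to the number of data points.  A simulated-
annealing search (geometric cooling, Gaussian proposals in log10 space for
positive-scale parameters) explores the parameter space; every evaluated
vector whose cost falls below the chi-square threshold is collected into
the acceptable set from which uncertainty envelopes are drawn.  A
Nelder-Mead polish refines the best vector found.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import ChipConfig, ModelParameters, OffsetParameters
from .data import TimeSeriesDataset, correct_sem
from .protocol import CultureProtocol, standard_protocol
from .simulate import SimulationError, simulate_protocol

__all__ = [
    "DEFAULT_FREE_PARAMETERS",
    "CalibrationProblem",
    "CalibrationResult",
    "AnnealSchedule",
    "chi2_threshold",
    "cost",
    "anneal",
    "uncertainty_envelope",
    "EnvelopeBands",
    "fit_insulin_decay",
]

#: the 12 experiment-specific parameters estimated from data by default
DEFAULT_FREE_PARAMETERS = (
    "E_G0", "CL_I_spheroids", "S_I0", "Imax_Si", "EC50_Si",
    "sigma_max", "alpha", "k_v", "dG_d1", "dG_d13", "dI_d1", "dI_d13",
)

_OFFSET_NAMES = ("dG_d1", "dG_d13", "dI_d1", "dI_d13")
_LOG_SCALE = {"E_G0", "CL_I_spheroids", "S_I0", "EC50_Si", "sigma_max",
              "alpha", "k_v"}


def chi2_threshold(alpha_sig: float, df: int) -> float:
    """(1 - alpha_sig) quantile of the chi-square distribution with df
    degrees of freedom; the model-adequacy bound for the cost."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if not 0 < alpha_sig < 1:
        raise ValueError("alpha_sig must lie in (0, 1)")
    return float(stats.chi2.ppf(1.0 - alpha_sig, df))


def fit_insulin_decay(times: Sequence[float],
                      concentrations: Sequence[float]) -> float:
    """Hepatic insulin elimination rate constant (1/h) from a washout
    series: minus the OLS slope of ln(concentration) against time."""
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two points")
    if (c <= 0).any():
        raise ValueError("concentrations must be positive")
    slope = np.polyfit(t, np.log(c), 1)[0]
    return float(-slope)


def _condition_key(culture_type: str, regime: str) -> str:
    return f"{culture_type}:{regime}"


@dataclass(frozen=True)
class _FreeParameter:
    name: str           # base parameter name
    condition: Optional[str]  # condition key for condition-specific offsets
    lo: float
    hi: float
    log: bool

    @property
    def label(self) -> str:
        return self.name if self.condition is None else f"{self.name}@{self.condition}"


def _default_bounds(name: str, base: ModelParameters) -> tuple[float, float]:
    if name == "Imax_Si":
        return (0.0, 1.0)
    if name in _OFFSET_NAMES:
        return (-3.0, 3.0)
    center = getattr(base, name)
    if center <= 0:
        raise ValueError(f"cannot build default log bounds for {name} <= 0")
    return (center * 1e-3, center * 1e3)


@dataclass
class _Condition:
    culture_type: str
    regime: str
    gtt_days: tuple
    protocol: CultureProtocol
    rows: pd.DataFrame

    @property
    def key(self) -> str:
        return _condition_key(self.culture_type, self.regime)


class CalibrationProblem:
    """A dataset plus the search space of an experiment-wise calibration.

    Conditions (culture type x regime) are simulated with shared model
    parameters; glucose offsets are condition-specific when more than one
    condition enters a joint fit, insulin offsets are always shared.
    Single-liver conditions are simulated with an empty pancreas
    compartment (no islets, no secretion).
    """

    def __init__(
        self,
        dataset: TimeSeriesDataset,
        config: Optional[ChipConfig] = None,
        base_params: Optional[ModelParameters] = None,
        free: Sequence[str] = DEFAULT_FREE_PARAMETERS,
        bounds: Optional[dict] = None,
        per_condition_glucose_offsets: bool = True,
        sim_dt: float = 0.02,
        track_volumes: bool = True,
    ):
        self.dataset = dataset
        self.config = config or ChipConfig()
        self.base_params = base_params or ModelParameters()
        self.sim_dt = sim_dt
        self.track_volumes = track_volumes
        bounds = bounds or {}

        self.conditions: list[_Condition] = []
        for ct, rg in dataset.conditions():
            days = dataset.gtt_days(ct, rg)
            rows = dataset.table[(dataset.table["culture_type"] == ct)
                                 & (dataset.table["regime"] == rg)]
            proto = standard_protocol(rg, OffsetParameters(), days,
                                      self.config)
            self.conditions.append(_Condition(ct, rg, days, proto, rows))

        multi = len(self.conditions) > 1 and per_condition_glucose_offsets
        self.free: list[_FreeParameter] = []
        for name in free:
            lo, hi = bounds.get(name, _default_bounds(name, self.base_params))
            log = name in _LOG_SCALE
            if name in ("dG_d1", "dG_d13") and multi:
                day = 1 if name.endswith("d1") else 13
                for cond in self.conditions:
                    if day in cond.gtt_days:
                        self.free.append(
                            _FreeParameter(name, cond.key, lo, hi, log))
            else:
                self.free.append(_FreeParameter(name, None, lo, hi, log))

    # -- vector <-> model mapping -------------------------------------------
    @property
    def labels(self) -> list[str]:
        return [f.label for f in self.free]

    @property
    def n_points(self) -> int:
        return self.dataset.n_points

    def decode(self, x: np.ndarray) -> tuple[ModelParameters, dict]:
        """Map a free-parameter vector to (ModelParameters, offsets map
        keyed by condition)."""
        param_updates = {}
        shared_offsets = {}
        cond_offsets: dict[str, dict] = {c.key: {} for c in self.conditions}
        for fp, v in zip(self.free, x):
            if fp.name in _OFFSET_NAMES:
                if fp.condition is None:
                    shared_offsets[fp.name] = float(v)
                else:
                    cond_offsets[fp.condition][fp.name] = float(v)
            else:
                param_updates[fp.name] = float(v)
        params = self.base_params.replace(**param_updates)
        offsets = {}
        for cond in self.conditions:
            d = dict(shared_offsets)
            d.update(cond_offsets[cond.key])
            offsets[cond.key] = OffsetParameters(**d)
        return params, offsets

    def encode(self, params: ModelParameters, offsets: Optional[dict] = None
               ) -> np.ndarray:
        x = np.empty(len(self.free))
        for i, fp in enumerate(self.free):
            if fp.name in _OFFSET_NAMES:
                if offsets is None:
                    x[i] = 0.0
                else:
                    key = fp.condition or self.conditions[0].key
                    x[i] = getattr(offsets[key], fp.name)
            else:
                x[i] = getattr(params, fp.name)
        return x

    # -- transformed (search) space -----------------------------------------
    def to_search(self, x: np.ndarray) -> np.ndarray:
        z = np.array(x, dtype=float)
        for i, fp in enumerate(self.free):
            if fp.log:
                z[i] = math.log10(max(z[i], 1e-300))
        return z

    def from_search(self, z: np.ndarray) -> np.ndarray:
        x = np.array(z, dtype=float)
        for i, fp in enumerate(self.free):
            if fp.log:
                x[i] = 10.0 ** x[i]
        return x

    def search_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([math.log10(f.lo) if f.log else f.lo for f in self.free])
        hi = np.array([math.log10(f.hi) if f.log else f.hi for f in self.free])
        return lo, hi

    def evaluate(self, x: np.ndarray) -> float:
        """Calibration cost of a free-parameter vector (natural scale)."""
        params, offsets = self.decode(x)
        return cost(params, offsets, self)


def _predictions(problem: CalibrationProblem, params: ModelParameters,
                 offsets: dict) -> dict:
    """Simulate every condition and index pooled predictions by
    (condition key, observable, time)."""
    lookup = {}
    for cond in problem.conditions:
        p = params if cond.culture_type == "co-culture" else params.as_single_liver()
        _, ms = simulate_protocol(
            p, offsets[cond.key], problem.config, cond.protocol,
            method="fixed", dt=problem.sim_dt,
            track_volumes=problem.track_volumes, record_trajectory=False)
        for m in ms:
            lookup[(cond.key, m.observable, round(m.time, 6))] = m.value
    return lookup


def cost(params: ModelParameters, offsets: Union[dict, OffsetParameters],
         problem: CalibrationProblem) -> float:
    """SEM-weighted sum of squared residuals over all data points.

    ``offsets`` may be a single :class:`OffsetParameters` (applied to every
    condition) or a mapping from condition key to offsets.  A failed
    simulation yields an infinite cost so the annealer simply rejects the
    proposal.
    """
    if isinstance(offsets, OffsetParameters):
        offsets = {c.key: offsets for c in problem.conditions}
    try:
        lookup = _predictions(problem, params, offsets)
    except (SimulationError, ValueError):
        return float("inf")
    V = 0.0
    for cond in problem.conditions:
        for _, row in cond.rows.iterrows():
            key = (cond.key, row["observable"], round(float(row["time_h"]), 6))
            if key not in lookup:
                raise KeyError(
                    f"no simulated observation matches data point {key}")
            resid = (row["mean"] - lookup[key]) / row["sem"]
            V += resid * resid
    return float(V)


@dataclass
class AnnealSchedule:
    """Simulated-annealing settings (all tunable).

    ``n_iter`` proposals are split across ``n_restarts`` independent
    chains.  Temperature starts at the initial cost (or ``T0``) and is
    multiplied by ``cooling`` every ``cooling_interval`` proposals.
    Gaussian proposals perturb all coordinates with standard deviation
    ``proposal_scale`` times each coordinate's search-space width.  A
    Nelder-Mead polish (``polish_maxfev`` evaluations) refines the best
    vector.
    """

    n_iter: int = 20000
    n_restarts: int = 5
    T0: Optional[float] = None
    cooling: float = 0.95
    cooling_interval: int = 100
    proposal_scale: float = 0.05
    polish: bool = True
    polish_maxfev: int = 2000
    max_accepted: int = 2000


@dataclass
class CalibrationResult:
    p_opt: dict
    params_opt: ModelParameters
    offsets_opt: dict
    V_opt: float
    df: int
    threshold: float
    passed: bool
    accepted: pd.DataFrame
    seed: int
    n_evaluations: int

    def to_json(self, path: Union[str, Path]) -> None:
        payload = dict(p_opt=self.p_opt, V_opt=self.V_opt, df=self.df,
                       threshold=self.threshold, passed=bool(self.passed),
                       seed=self.seed, n_evaluations=self.n_evaluations)
        Path(path).write_text(json.dumps(payload, indent=2))


def anneal(problem: CalibrationProblem, seed: int,
           schedule: Optional[AnnealSchedule] = None) -> CalibrationResult:
    """Stochastic minimization of the calibration cost.

    Reproducible for a given seed.  Every evaluated vector with a cost
    below the chi-square threshold joins the accepted set; the result is
    flagged not-passed when no vector beats the threshold (the model is
    rejected for this dataset).
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    lo, hi = problem.search_bounds()
    width = hi - lo
    threshold = chi2_threshold(0.05, problem.n_points)

    accepted_rows: list[dict] = []
    n_eval = 0

    def f(z: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        if np.any(z < lo - 1e-12) or np.any(z > hi + 1e-12):
            return float("inf")
        x = problem.from_search(z)
        try:
            V = problem.evaluate(x)
        except (ValueError, KeyError):
            return float("inf")
        if V < threshold:
            row = dict(zip(problem.labels, x))
            row["V"] = V
            accepted_rows.append(row)
        return V

    best_z, best_V = None, float("inf")
    iters_per_restart = max(1, schedule.n_iter // max(1, schedule.n_restarts))
    for _ in range(schedule.n_restarts):
        z = lo + rng.random(len(lo)) * width
        V = f(z)
        if V < best_V or best_z is None:
            best_z, best_V = z.copy(), V
        T = schedule.T0 if schedule.T0 is not None else max(V, 1.0)
        if not np.isfinite(T):
            T = 1e6
        for it in range(iters_per_restart):
            z_new = z + rng.normal(0.0, schedule.proposal_scale * width)
            z_new = np.clip(z_new, lo, hi)
            V_new = f(z_new)
            dV = V_new - V
            if dV <= 0 or rng.random() < math.exp(-min(dV / max(T, 1e-12), 700)):
                z, V = z_new, V_new
                if V < best_V:
                    best_z, best_V = z.copy(), V
            if (it + 1) % schedule.cooling_interval == 0:
                T *= schedule.cooling

    if schedule.polish and best_z is not None and np.isfinite(best_V):
        res = optimize.minimize(
            f, best_z, method="Nelder-Mead",
            bounds=list(zip(lo, hi)),
            options=dict(maxfev=schedule.polish_maxfev, xatol=1e-6,
                         fatol=1e-8))
        if np.isfinite(res.fun) and res.fun <= best_V:
            best_z, best_V = res.x, float(res.fun)

    x_best = problem.from_search(best_z)
    params_opt, offsets_opt = problem.decode(x_best)
    accepted = pd.DataFrame(accepted_rows,
                            columns=problem.labels + ["V"])
    if len(accepted) > schedule.max_accepted:
        stride = int(np.ceil(len(accepted) / schedule.max_accepted))
        keep = accepted.iloc[::stride]
        # never thin away the optimum
        if keep["V"].min() > accepted["V"].min():
            keep = pd.concat([keep,
                              accepted.loc[[accepted["V"].idxmin()]]])
        accepted = keep.reset_index(drop=True)
    return CalibrationResult(
        p_opt=dict(zip(problem.labels, x_best)),
        params_opt=params_opt,
        offsets_opt=offsets_opt,
        V_opt=best_V,
        df=problem.n_points,
        threshold=threshold,
        passed=bool(best_V < threshold),
        accepted=accepted,
        seed=seed,
        n_evaluations=n_eval,
    )


@dataclass
class EnvelopeBands:
    """Pointwise min/max bands of observables and mechanistic variables
    over a set of acceptable parameter vectors."""

    times: np.ndarray
    lo: dict
    hi: dict

    def width(self, variable: str) -> np.ndarray:
        return self.hi[variable] - self.lo[variable]


ENVELOPE_VARIABLES = ("G_pooled", "I_pooled", "S_I", "sigma", "V_beta",
                      "G_int", "G_slow")


def uncertainty_envelope(
    accepted: Iterable,
    config: ChipConfig,
    protocol: CultureProtocol,
    variables: Sequence[str] = ENVELOPE_VARIABLES,
    **sim_kwargs,
) -> EnvelopeBands:
    """Simulate each accepted parameter vector and take pointwise extrema.

    ``accepted`` yields :class:`ModelParameters` or
    ``(ModelParameters, OffsetParameters)`` pairs.  Adding a vector can
    only widen the bands; the optimum's trajectory always lies inside.
    """
    entries = list(accepted)
    if not entries:
        raise ValueError("accepted set is empty")
    sim_kwargs.setdefault("method", "fixed")
    stacks: dict[str, list] = {v: [] for v in variables}
    times = None
    for entry in entries:
        params, offsets = entry if isinstance(entry, tuple) else (entry, None)
        traj, _ = simulate_protocol(params, offsets, config, protocol,
                                    **sim_kwargs)
        if times is None:
            times = traj.times
        for v in variables:
            stacks[v].append(getattr(traj, v))
    lo = {v: np.vstack(s).min(axis=0) for v, s in stacks.items()}
    hi = {v: np.vstack(s).max(axis=0) for v, s in stacks.items()}
    return EnvelopeBands(times=times, lo=lo, hi=hi)


def result_accepted_entries(result: CalibrationResult,
                            problem: CalibrationProblem,
                            max_entries: int = 50) -> list:
    """Decode (a deterministic thinning of) the accepted set of a
    calibration result into (params, offsets-for-first-condition) pairs
    ready for :func:`uncertainty_envelope`."""
    df = result.accepted
    if len(df) == 0:
        return []
    stride = max(1, len(df) // max_entries)
    entries = []
    for _, row in df.iloc[::stride].iterrows():
        x = np.array([row[l] for l in problem.labels])
        params, offsets = problem.decode(x)
        entries.append((params, offsets[problem.conditions[0].key]))
    return entries
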