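"""Domain types: chip operating conditions, model parameters and system state.

Units are fixed globally throughout the package: amounts in mmol (glucose)
and mIU (insulin), volumes in L, time in h.  Concentrations are therefore
mmol/L (identical to mM) and mIU/L.  No unit conversion happens inside the
model core; helpers for converting experimentalists' units (uL/min flow
rates, islet geometry) live at the edges of this module.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "ChipConfig",
    "ModelParameters",
    "OffsetParameters",
    "SystemState",
    "STATE_FIELDS",
    "flow_rate_l_per_h",
    "beta_cell_volume_from_islets",
]


def flow_rate_l_per_h(ul_per_min: float) -> float:
    """Convert a pump flow rate in uL/min to L/h."""
    return ul_per_min * 60.0 / 1.0e6


def beta_cell_volume_from_islets(
    n_islets: int = 10,
    islet_diameter_m: float = 150e-6,
    beta_fraction: float = 0.5,
) -> float:
    """Total beta-cell volume (L) from islet count and geometry.

    Each islet is treated as a sphere of the given diameter with a fixed
    volume fraction of insulin-secreting beta cells.  The defaults (10
    reaggregated human islets of 150 um diameter, ~50% beta cells) give
    8.8e-9 L, the initial beta-cell volume of the chip co-culture.
    """
    r = islet_diameter_m / 2.0
    volume_m3 = n_islets * beta_fraction * (4.0 / 3.0) * math.pi * r**3
    return volume_m3 * 1.0e3  # m^3 -> L


class _Serializable:
    """Flat key-value (YAML/JSON) serialization shared by the config types."""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict):
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
        return cls(**d)

    def to_file(self, path: Union[str, Path]) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_file(cls, path: Union[str, Path]):
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)

    def replace(self, **changes):
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class ChipConfig(_Serializable):
    """Physical operating conditions of the two-compartment chip.

    Defaults are the chip's nominal operating conditions: 300 uL of medium
    in each culture compartment plus 5 uL in the connecting channel, a mean
    inter-compartment flow of 2.96e-4 L/h (4.94 uL/min), 3.4e-6 L of
    hepatocytes and 15 uL withdrawn per compartment at each sampling.
    """

    V_m_liver: float = 3.0e-4
    V_m_pancreas: float = 3.0e-4
    V_hepaRG: float = 3.4e-6
    Q: float = 2.96e-4
    V_sample_liver: float = 1.5e-5
    V_sample_pancreas: float = 1.5e-5
    V_channel: float = 5.0e-6

    def __post_init__(self):
        for name in ("V_m_liver", "V_m_pancreas", "V_hepaRG", "Q",
                     "V_sample_liver", "V_sample_pancreas"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.V_channel < 0:
            raise ValueError("V_channel must be nonnegative")
        if self.V_sample_liver >= self.V_m_liver:
            raise ValueError("V_sample_liver must be smaller than V_m_liver")
        if self.V_sample_pancreas >= self.V_m_pancreas:
            raise ValueError("V_sample_pancreas must be smaller than V_m_pancreas")

    @property
    def total_medium_volume(self) -> float:
        """Total circulating medium (both compartments plus channel), L."""
        return self.V_m_liver + self.V_m_pancreas + self.V_channel

    @property
    def turnover_time_h(self) -> float:
        """Mean medium turnover time, total medium volume / flow rate (h)."""
        return self.total_medium_volume / self.Q


@dataclass(frozen=True)
class ModelParameters(_Serializable):
    """Kinetic and physiological constants of the glucose-insulin model.

    Fields
    ------
    E_G0 : insulin-independent hepatic glucose disposal rate (1/h)
    CL_I_spheroids : hepatic insulin elimination rate constant (1/h)
    S_I0 : insulin sensitivity at co-culture start (L/mIU/h)
    Imax_Si : maximal fractional reduction of insulin sensitivity (-)
    EC50_Si : excess-glucose integral at half-maximal reduction (mmol*h/L)
    G_normo : normoglycemic threshold (mmol/L)
    sigma_max : initial beta-cell insulin secretion rate per unit volume
        (mIU/L/h)
    alpha : shape parameter of the sigmoidal secretion decay (h^2)
    EC50_I : glucose at half-maximal insulin secretion (mmol/L)
    d0 : beta-cell death rate at zero glucose (1/h)
    r1, r2 : linear and quadratic glucose coefficients of the net beta-cell
        growth rate (L/mmol/h and L^2/mmol^2/h).  These are the identifiable
        sums of the replication and apoptosis contributions; the four
        addends are never represented separately.
    k_v : species scaling factor for the beta-cell rate of change (-)
    tau_slow : time constant averaging pancreas glucose into the slow
        glucose signal (h)
    EGP : endogenous glucose production rate (mmol/L/h); negligible for the
        hepatic spheroids and zero by default, the slot is retained so that
        the in-vivo translation caveat can be explored
    V_beta0 : total beta-cell volume at co-culture start (L)
    """

    E_G0: float = 1.47
    CL_I_spheroids: float = 17.81
    S_I0: float = 5.0e-3
    Imax_Si: float = 0.9
    EC50_Si: float = 500.0
    G_normo: float = 5.5
    sigma_max: float = 6.0e6
    alpha: float = 3.0e4
    EC50_I: float = 7.86
    d0: float = 2.5e-3
    r1: float = 6.3e-4
    r2: float = 3.24e-5
    k_v: float = 1.0
    tau_slow: float = 500.0
    EGP: float = 0.0
    V_beta0: float = 8.8e-9

    def __post_init__(self):
        if not 0.0 <= self.Imax_Si <= 1.0:
            raise ValueError("Imax_Si must lie in [0, 1]")
        for name in ("E_G0", "CL_I_spheroids", "S_I0", "EC50_Si", "G_normo",
                     "sigma_max", "alpha", "EC50_I", "d0", "r1", "r2",
                     "tau_slow", "V_beta0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.tau_slow == 0:
            raise ValueError("tau_slow must be positive")
        # with beta-cell dynamics enabled the growth quadratic must have two
        # real roots, otherwise no glucose level sustains the beta-cell mass
        if self.k_v > 0 and self.V_beta0 > 0 and self.r2 > 0:
            if self.r1**2 <= 4.0 * self.r2 * self.d0:
                raise ValueError(
                    "r1^2 must exceed 4*r2*d0 when beta-cell dynamics are enabled"
                )

    def as_single_liver(self) -> "ModelParameters":
        """Parameters for a single-liver culture: the pancreas compartment is
        kept empty but flow-connected, i.e. no islets and no secretion."""
        return self.replace(V_beta0=0.0, sigma_max=0.0)


@dataclass(frozen=True)
class OffsetParameters(_Serializable):
    """Additive measurement-protocol offsets at the tagged GTT exchanges.

    dG_* are glucose offsets (mmol/L) and dI_* insulin offsets (mIU/L)
    applied to the fresh medium of the exchanges that initiate the day-1 and
    day-13 glucose tolerance tests.  They absorb systematic dosing errors of
    the media exchange and default to zero.
    """

    dG_d1: float = 0.0
    dG_d13: float = 0.0
    dI_d1: float = 0.0
    dI_d13: float = 0.0


#: ordering of the dynamic state vector used throughout the package
STATE_FIELDS = (
    "NG_liver",
    "NG_pancreas",
    "NI_liver",
    "NI_pancreas",
    "G_int",
    "G_slow",
    "V_beta",
)


@dataclass
class SystemState:
    """Instantaneous state of the chip: molecule amounts and slow variables.

    ``NG_*`` are glucose amounts (mmol) and ``NI_*`` insulin amounts (mIU)
    in each compartment's medium; ``G_int`` is the running integral of
    liver-compartment glucose above the normoglycemic threshold (mmol*h/L);
    ``G_slow`` the long-term average pancreas glucose (mmol/L); ``V_beta``
    the total beta-cell volume (L).  ``V_m_liver_now``/``V_m_pancreas_now``
    track the current medium volumes when sampling-induced volume loss is
    modelled.
    """

    t: float = 0.0
    NG_liver: float = 0.0
    NG_pancreas: float = 0.0
    NI_liver: float = 0.0
    NI_pancreas: float = 0.0
    G_int: float = 0.0
    G_slow: float = 0.0
    V_beta: float = 0.0
    V_m_liver_now: float = 3.0e-4
    V_m_pancreas_now: float = 3.0e-4

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in STATE_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be nonnegative")
        if self.V_m_liver_now <= 0 or self.V_m_pancreas_now <= 0:
            raise ValueError("medium volumes must be positive")

    # -- concentration views -------------------------------------------------
    @property
    def G_liver(self) -> float:
        return self.NG_liver / self.V_m_liver_now

    @property
    def G_pancreas(self) -> float:
        return self.NG_pancreas / self.V_m_pancreas_now

    @property
    def I_liver(self) -> float:
        return self.NI_liver / self.V_m_liver_now

    @property
    def I_pancreas(self) -> float:
        return self.NI_pancreas / self.V_m_pancreas_now

    # -- array round trip ----------------------------------------------------
    def as_vector(self):
        import numpy as np

        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_vector(cls, t, y, V_m_liver, V_m_pancreas) -> "SystemState":
        values = dict(zip(STATE_FIELDS, (float(v) for v in y)))
        return cls(t=float(t), V_m_liver_now=float(V_m_liver),
                   V_m_pancreas_now=float(V_m_pancreas), **values)

    def copy(self) -> "SystemState":
        return dataclasses.replace(self)
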