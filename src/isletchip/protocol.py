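"""The 15-day culture schedule as an ordered discrete-event timeline.

Time origin: t = 0 h is the start of the co-culture; "day k" events occur at
t = 24*k h.  Medium is exchanged first after 24 h and then every 48 h over
the 15-day culture (t = 24, 72, ..., 312 h).  Glucose tolerance tests (GTTs)
coincide with the day-1 and day-13 exchanges; the day-13 GTT always doses
11 mM regardless of regime, while the day-1 GTT doses the regime's own
glucose level.  Pooled 15-uL samples are withdrawn from each compartment at
GTT start + {0, 8, 24, 48} h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .config import ChipConfig, OffsetParameters

__all__ = [
    "GlycemicRegime",
    "HYPER", "NORMO", "HYPO", "REGIMES",
    "MediaExchangeEvent",
    "SamplingEvent",
    "CultureProtocol",
    "standard_protocol",
    "periodic_observation_protocol",
    "GTT_SAMPLE_OFFSETS",
]

#: sampling offsets (h) relative to the start of a glucose tolerance test
GTT_SAMPLE_OFFSETS = (0.0, 8.0, 24.0, 48.0)

#: exchange schedule (h): first after 24 h, then every 48 h over 15 days
EXCHANGE_TIMES = tuple(24.0 + 48.0 * k for k in range(7))

#: glucose dose (mmol/L) of the day-13 GTT, identical for every regime
GTT_D13_DOSE = 11.0


@dataclass(frozen=True)
class GlycemicRegime:
    """A glycemic culture regime: the glucose concentration of fresh medium."""

    name: str
    G_dose: float

    def __post_init__(self):
        expected = {"hyper": 11.0, "normo": 5.5, "hypo": 2.8}
        if self.name in expected and self.G_dose != expected[self.name]:
            raise ValueError(
                f"regime {self.name!r} must dose {expected[self.name]} mM"
            )


HYPER = GlycemicRegime("hyper", 11.0)
NORMO = GlycemicRegime("normo", 5.5)
HYPO = GlycemicRegime("hypo", 2.8)
REGIMES = {r.name: r for r in (HYPER, NORMO, HYPO)}


def _as_regime(regime: Union[str, GlycemicRegime]) -> GlycemicRegime:
    if isinstance(regime, GlycemicRegime):
        return regime
    try:
        return REGIMES[regime]
    except KeyError:
        raise ValueError(f"unknown regime {regime!r}") from None


@dataclass(frozen=True)
class MediaExchangeEvent:
    """Replacement of both compartments' medium with fresh medium.

    The fresh medium is insulin-free (I_new = 0) in the standard protocol;
    additive offsets dG/dI model systematic dosing errors at the exchanges
    that start a GTT (``starts_gtt`` is then "d1" or "d13").
    """

    time: float
    G_new: float
    I_new: float = 0.0
    dG: float = 0.0
    dI: float = 0.0
    starts_gtt: Optional[str] = None
    # exchanges sort after ordinary samples and before the post-exchange
    # 0-h GTT sample taken immediately after the fresh medium is added
    order: int = 1


@dataclass(frozen=True)
class SamplingEvent:
    """Withdrawal of medium from each compartment for measurement."""

    time: float
    volume_per_compartment: float = 1.5e-5
    pooled: bool = True
    order: int = 0  # 0: before a coincident exchange; 2: right after it


Event = Union[MediaExchangeEvent, SamplingEvent]


@dataclass(frozen=True)
class CultureProtocol:
    regime: GlycemicRegime
    events: tuple
    duration: float = 360.0

    def __post_init__(self):
        keys = [(e.time, e.order) for e in self.events]
        if keys != sorted(keys):
            raise ValueError("events must be time-ordered")
        if any(k1 == k2 for k1, k2 in zip(keys, keys[1:])):
            raise ValueError("events must be strictly ordered")
        if self.events and self.duration < self.events[-1].time:
            raise ValueError("duration must cover the last event")

    @property
    def exchanges(self) -> tuple:
        return tuple(e for e in self.events
                     if isinstance(e, MediaExchangeEvent))

    @property
    def samplings(self) -> tuple:
        return tuple(e for e in self.events if isinstance(e, SamplingEvent))

    # -- plain-text audit table ----------------------------------------------
    def to_table(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            if isinstance(e, MediaExchangeEvent):
                rows.append(dict(time_h=e.time, event_type="exchange",
                                 G_new=e.G_new, I_new=e.I_new, dG=e.dG,
                                 dI=e.dI, volume_L=float("nan"),
                                 pooled=""))
            else:
                rows.append(dict(time_h=e.time, event_type="sampling",
                                 G_new=float("nan"), I_new=float("nan"),
                                 dG=float("nan"), dI=float("nan"),
                                 volume_L=e.volume_per_compartment,
                                 pooled=bool(e.pooled)))
        return pd.DataFrame(rows)

    def save_table(self, path: Union[str, Path]) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


def standard_protocol(
    regime: Union[str, GlycemicRegime],
    offsets: Optional[OffsetParameters] = None,
    gtt_days: Sequence[int] = (1, 13),
    config: Optional[ChipConfig] = None,
    duration: float = 360.0,
) -> CultureProtocol:
    """The standard 15-day culture with GTTs on the requested days.

    Exchanges at t = 24, 72, ..., 312 h dose the regime's glucose level,
    except the day-13 exchange which doses 11 mM for every regime.  The
    day-1 (t = 24 h) and day-13 (t = 312 h) exchanges are tagged as GTT
    starts when requested and carry the corresponding offsets; pooled
    samples follow at GTT start + {0, 8, 24, 48} h.
    """
    regime = _as_regime(regime)
    offsets = offsets or OffsetParameters()
    config = config or ChipConfig()
    unknown = set(gtt_days) - {1, 13}
    if unknown:
        raise ValueError(f"GTTs supported on days 1 and 13 only, got {sorted(unknown)}")

    gtt_start = {1: 24.0, 13: 312.0}
    events: list[Event] = []
    for t in EXCHANGE_TIMES:
        G_new = GTT_D13_DOSE if t == 312.0 else regime.G_dose
        dG = dI = 0.0
        starts = None
        if t == 24.0 and 1 in gtt_days:
            starts, dG, dI = "d1", offsets.dG_d1, offsets.dI_d1
        elif t == 312.0 and 13 in gtt_days:
            starts, dG, dI = "d13", offsets.dG_d13, offsets.dI_d13
        events.append(MediaExchangeEvent(time=t, G_new=G_new, dG=dG, dI=dI,
                                         starts_gtt=starts))
    vol = min(config.V_sample_liver, config.V_sample_pancreas)
    for day in gtt_days:
        start = gtt_start[day]
        for off in GTT_SAMPLE_OFFSETS:
            # the 0-h sample is taken immediately after the exchange that
            # starts the GTT (offsets applied first)
            order = 2 if off == 0.0 else 0
            events.append(SamplingEvent(time=start + off,
                                        volume_per_compartment=vol,
                                        pooled=True, order=order))
    events.sort(key=lambda e: (e.time, e.order))
    return CultureProtocol(regime=regime, events=tuple(events),
                           duration=duration)


def periodic_observation_protocol(
    regime: Union[str, GlycemicRegime],
    offsets: Optional[OffsetParameters] = None,
    gtt_days: Sequence[int] = (1, 13),
    config: Optional[ChipConfig] = None,
) -> CultureProtocol:
    """Standard protocol plus per-compartment samples 48 h after each
    exchange between days 3 and 13 (i.e. immediately before the next
    exchange), used to observe compartment-wise long-term dynamics."""
    base = standard_protocol(regime, offsets, gtt_days, config)
    config = config or ChipConfig()
    vol = min(config.V_sample_liver, config.V_sample_pancreas)
    # order=-1: taken just before any coincident GTT sample and exchange
    extra = [SamplingEvent(time=t, volume_per_compartment=vol, pooled=False,
                           order=-1)
             for t in EXCHANGE_TIMES if t >= 72.0]
    events = sorted(base.events + tuple(extra), key=lambda e: (e.time, e.order))
    return CultureProtocol(regime=base.regime, events=tuple(events),
                           duration=base.duration)


def single_dose_protocol(
    dose: float,
    duration: float,
    sample_every: float = 0.25,
    regime_name: str = "bolus",
) -> CultureProtocol:
    """A single glucose load at t = 0 with periodic pooled zero-volume
    sampling; used for the human-scale meal-response simulation."""
    regime = GlycemicRegime(regime_name, dose)
    n = int(duration / sample_every)
    events = tuple(SamplingEvent(time=k * sample_every,
                                 volume_per_compartment=0.0, pooled=True,
                                 order=2 if k == 0 else 0)
                   for k in range(n + 1))
    return CultureProtocol(regime=regime, events=events, duration=duration)
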