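"""Discrete slurry-management events: emptying, retention, enrichment.

Slurry is produced at a constant rate F_in and removed instantaneously the
moment the stored mass reaches the storage capacity M_m_max.  A residual
fraction f_resid stays behind as inoculum for the next fill cycle.  Microbes
can be preferentially retained (biofilms on walls and in sediment): the
enrichment factor a_enrich adds to the log-odds of retention, so a group's
retained fraction is logistic(logit(f_resid) + a_enrich).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reactor import SlurryState

__all__ = [
    "ManagementScheme",
    "RemovalEvent",
    "retention_fraction",
    "apply_removal",
    "next_removal_time",
]


@dataclass(frozen=True)
class ManagementScheme:
    """Production rate, storage capacity and emptying behaviour.

    mode:
      * ``"threshold"`` — removal fires exactly when M_m reaches M_m_max;
      * ``"forced-mass-series"`` — slurry mass follows an imposed time
        series (the forcings must carry it); decreases in the series are
        treated as removal events, increases as additions.
    """

    F_in: float = 1000.0        # kg d^-1
    M_m_max: float = 33333.0    # kg
    f_resid: float = 0.10
    a_enrich: float = 0.0
    mode: str = "threshold"

    def __post_init__(self) -> None:
        if not 0 < self.f_resid < 1:
            raise ValueError(f"f_resid must lie strictly in (0, 1), got {self.f_resid}")
        if self.M_m_max <= 0:
            raise ValueError("M_m_max must be positive")
        if self.F_in < 0:
            raise ValueError("F_in must be >= 0")
        if self.mode not in ("threshold", "forced-mass-series"):
            raise ValueError(f"unknown management mode {self.mode!r}")


@dataclass
class RemovalEvent:
    """Record of one emptying event (masses removed, per pool)."""

    time: float
    M_m_before: float
    M_m_after: float
    removed: dict = field(default_factory=dict)   # pool name -> mass removed
    f_resid: float = 0.0
    f_resid_X: np.ndarray = field(default_factory=lambda: np.zeros(0))


def retention_fraction(f_resid: float, a_enrich: float) -> float:
    """Fraction of a microbial population retained at emptying.

    logistic(logit(f_resid) + a_enrich); equal to f_resid when a_enrich = 0
    and monotone increasing in a_enrich.
    """
    if not 0 < f_resid < 1:
        raise ValueError(f"f_resid must lie strictly in (0, 1), got {f_resid}")
    z = math.log(f_resid / (1.0 - f_resid)) + a_enrich
    return 1.0 / (1.0 + math.exp(-z))


def apply_removal(
    s: SlurryState,
    scheme: ManagementScheme,
    time: float = 0.0,
    f_resid: float | None = None,
) -> tuple[SlurryState, RemovalEvent]:
    """Instantaneous slurry removal.

    Slurry mass and the solute/substrate pools (S_p, VFA, SO4, sulfide, TAN)
    are scaled by ``f_resid``; each biomass pool by
    ``retention_fraction(f_resid, a_enrich)``.  Cumulative emission counters
    are untouched.  Returns the post-event state and an event record with the
    removed masses.  ``f_resid`` overrides the scheme value (used by the
    forced-mass-series mode where the removed fraction is inferred).
    """
    if s.M_m <= 0:
        raise ValueError("cannot apply removal to an empty storage")
    f = scheme.f_resid if f_resid is None else f_resid
    f_X = retention_fraction(f, scheme.a_enrich)

    new = SlurryState(
        M_m=s.M_m * f,
        S_p=s.S_p * f,
        VFA=s.VFA * f,
        SO4=s.SO4 * f,
        sulfide=s.sulfide * f,
        TAN=s.TAN * f,
        X=s.X * f_X,
        CH4_cum=s.CH4_cum,
        CO2_cum=s.CO2_cum,
        H2S_emitted_cum=s.H2S_emitted_cum,
    )
    event = RemovalEvent(
        time=time,
        M_m_before=s.M_m,
        M_m_after=new.M_m,
        removed={
            "M_m": s.M_m - new.M_m,
            "S_p": s.S_p - new.S_p,
            "VFA": s.VFA - new.VFA,
            "SO4": s.SO4 - new.SO4,
            "sulfide": s.sulfide - new.sulfide,
            "TAN": s.TAN - new.TAN,
            "X": s.X - new.X,
        },
        f_resid=f,
        f_resid_X=np.full_like(np.asarray(s.X, dtype=float), f_X),
    )
    return new, event


def next_removal_time(M_m: float, scheme: ManagementScheme) -> float:
    """Days until the store fills from mass M_m at constant inflow.

    Returns ``inf`` when F_in = 0 (the threshold never triggers).
    """
    if M_m > scheme.M_m_max:
        raise ValueError("slurry mass exceeds storage capacity")
    if scheme.F_in == 0:
        return math.inf
    return (scheme.M_m_max - M_m) / scheme.F_in
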