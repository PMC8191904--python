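"""Temperature, substrate and inhibition responses of the biological rates.

Every biological rate in the slurry model is the product of three responses:

* a cardinal temperature model (CTM1) giving the maximum specific rate as a
  function of temperature between a group's cardinal temperatures,
* a Monod (or double-Monod, for sulfate reducers) substrate limitation with a
  half-saturation constant that itself declines exponentially with
  temperature, and
* a product of dimensionless inhibition factors (pH, free ammonia NH3,
  ammonium NH4+, hydrogen sulfide H2S), each in [0, 1].

This module is purely functional: it knows nothing about reactor state or
time.  Units are the model's native ones throughout: g COD-S for substrate,
g COD-B for biomass, g per kg slurry for concentrations, days for time,
degrees Celsius for temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CardinalParams",
    "KSTemperatureParams",
    "InhibitionConstants",
    "MicrobialGroup",
    "cardinal_rate",
    "ks_at_temperature",
    "qmax_opt_from_linear_rule",
    "methanogen_uptake_rate",
    "sulfate_reduction_rate",
    "ph_inhibition",
    "noncompetitive_inhibition",
    "inhibition_product",
    "speciate_tan",
    "speciate_sulfide",
    "nh4_pka",
    "h2s_pka1",
]

# Linear q_max,opt assignment: 0 at 0 degC rising to 8 g COD-S g COD-B^-1 d^-1
# at 40 degC, extrapolated linearly above.
QMAX_ANCHOR_T = 40.0
QMAX_ANCHOR_RATE = 8.0


@dataclass(frozen=True)
class CardinalParams:
    """Cardinal temperatures and the optimum rate of a CTM1 response.

    ``rate_opt`` carries the units of whatever rate the response governs
    (d^-1 for the hydrolysis constant alpha, g COD-S g COD-B^-1 d^-1 for a
    group's q_max).
    """

    T_min: float
    T_opt: float
    T_max: float
    rate_opt: float

    def __post_init__(self) -> None:
        if not (self.T_min < self.T_opt < self.T_max):
            raise ValueError(
                f"cardinal temperatures must satisfy T_min < T_opt < T_max, "
                f"got ({self.T_min}, {self.T_opt}, {self.T_max})"
            )
        if self.rate_opt < 0:
            raise ValueError(f"rate_opt must be >= 0, got {self.rate_opt}")


@dataclass(frozen=True)
class KSTemperatureParams:
    """Shared parameters of the exponential K_S(T) = k1 * exp(-k2 * T) law.

    k1 is the half-saturation constant at 0 degC (g COD-S per kg slurry),
    k2 the decline rate per degree Celsius.  Group-to-group differences in
    substrate affinity enter through a dimensionless per-group multiplier
    (``KS_coef``), not through separate (k1, k2) pairs.
    """

    k1: float = 1.0
    k2: float = 0.05

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"k1 and k2 must be positive, got ({self.k1}, {self.k2})")


@dataclass(frozen=True)
class InhibitionConstants:
    """Per-group inhibition parameters.

    The pH response is a two-sided limit function parameterised by a lower
    and upper bound, normalised so it equals exactly 1 at the group's pH
    optimum (the midpoint of the bounds).  NH3, NH4+ and H2S act through
    noncompetitive factors I = 1 / (1 + C / K_I); a K_I of ``inf`` disables
    that inhibitor for the group.
    """

    pH_LL: float = 6.0          # lower pH bound
    pH_UL: float = 8.5          # upper pH bound
    K_I_NH3: float = 0.10       # g NH3-N per kg slurry
    K_I_NH4: float = 5.0        # g NH4-N per kg slurry
    K_I_H2S: float = 0.10       # g H2S-S per kg slurry

    def __post_init__(self) -> None:
        if not self.pH_LL < self.pH_UL:
            raise ValueError("pH_LL must be below pH_UL")
        for name in ("K_I_NH3", "K_I_NH4", "K_I_H2S"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pH_opt(self) -> float:
        return 0.5 * (self.pH_LL + self.pH_UL)


@dataclass(frozen=True)
class MicrobialGroup:
    """Kinetic, thermal and inhibition parameters of one population.

    ``cardinal.rate_opt`` houses q_max,opt.  ``KS_coef`` multiplies the shared
    K_S(T) law.  ``C_X_in`` is the concentration of this group's active
    biomass in the influent slurry (g COD-B per kg); ``X_init`` its initial
    biomass in the store (g COD-B).
    """

    id: str
    cardinal: CardinalParams
    Y: float = 0.05                      # g COD-B per g COD-S
    k_d: float = 0.02                    # d^-1
    KS_coef: float = 1.0
    KS_SO4: float = 0.05                 # g SO4-S per kg; sulfate reducers only
    inhibition: InhibitionConstants = field(default_factory=InhibitionConstants)
    C_X_in: float = 0.001                # g COD-B per kg slurry
    X_init: float = 0.0                  # g COD-B
    is_sulfate_reducer: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.Y < 1:
            raise ValueError(f"yield Y must lie in (0, 1), got {self.Y}")
        if self.k_d < 0:
            raise ValueError("decay rate k_d must be >= 0")
        if self.KS_coef <= 0:
            raise ValueError("KS_coef must be positive")
        if self.C_X_in < 0 or self.X_init < 0:
            raise ValueError("biomass concentrations must be >= 0")
        if self.is_sulfate_reducer and self.KS_SO4 <= 0:
            raise ValueError("KS_SO4 must be positive for a sulfate reducer")

    def with_(self, **kw) -> "MicrobialGroup":
        return replace(self, **kw)


def cardinal_rate(T, p: CardinalParams):
    """CTM1 rate at temperature ``T`` (degC); 0 outside (T_min, T_max).

    The raw CTM1 polynomial changes sign outside the cardinal interval, which
    has no biological meaning, so the response is clamped to zero there.
    Accepts scalars or arrays.
    """
    T = np.asarray(T, dtype=float)
    num = (T - p.T_max) * (T - p.T_min) ** 2
    den = (p.T_opt - p.T_min) * (
        (p.T_opt - p.T_min) * (T - p.T_opt)
        - (p.T_opt - p.T_max) * (p.T_opt + p.T_min - 2.0 * T)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(den != 0.0, p.rate_opt * num / np.where(den != 0.0, den, 1.0), 0.0)
    rate = np.where((T <= p.T_min) | (T >= p.T_max), 0.0, rate)
    rate = np.maximum(rate, 0.0)
    return rate if rate.ndim else float(rate)


def ks_at_temperature(T, KS_coef: float, p: KSTemperatureParams):
    """Half-saturation constant K_S = KS_coef * k1 * exp(-k2 * T), g COD-S/kg."""
    if KS_coef <= 0:
        raise ValueError("KS_coef must be positive")
    T = np.asarray(T, dtype=float)
    ks = KS_coef * p.k1 * np.exp(-p.k2 * T)
    return ks if ks.ndim else float(ks)


def qmax_opt_from_linear_rule(
    T_opt: float,
    anchor_T: float = QMAX_ANCHOR_T,
    anchor_rate: float = QMAX_ANCHOR_RATE,
) -> float:
    """Default q_max,opt for a group: linear in T_opt through the origin.

    The line runs from 0 at 0 degC to ``anchor_rate`` (8 g COD-S g COD-B^-1
    d^-1) at ``anchor_T`` (40 degC) and is extrapolated beyond the anchor.
    """
    if T_opt < 0:
        raise ValueError(f"T_opt must be >= 0 for the linear rule, got {T_opt}")
    return anchor_rate * T_opt / anchor_T


def methanogen_uptake_rate(C_VFA, K_S, q_max, X, I_product=1.0):
    """Monod VFA-consumption magnitude of one methanogen group, g COD-S d^-1.

    Returns the (nonnegative) consumption magnitude; the reactor applies the
    Petersen-matrix signs.
    """
    _check_inhibition_value(I_product)
    C_VFA = np.maximum(np.asarray(C_VFA, dtype=float), 0.0)
    r = q_max * C_VFA / (K_S + C_VFA) * X * I_product
    return r if np.ndim(r) else float(r)


def sulfate_reduction_rate(C_VFA, C_SO4, K_S, K_S_SO4, q_max, X_sr, I_product=1.0):
    """Double-Monod VFA consumption by sulfate reducers, g COD-S d^-1."""
    _check_inhibition_value(I_product)
    C_VFA = np.maximum(np.asarray(C_VFA, dtype=float), 0.0)
    C_SO4 = np.maximum(np.asarray(C_SO4, dtype=float), 0.0)
    r = (
        q_max
        * C_VFA / (K_S + C_VFA)
        * C_SO4 / (K_S_SO4 + C_SO4)
        * X_sr
        * I_product
    )
    return r if np.ndim(r) else float(r)


def _check_inhibition_value(I) -> None:
    if np.any(np.asarray(I) < 0) or np.any(np.asarray(I) > 1):
        raise ValueError("inhibition product must lie in [0, 1]")


def ph_inhibition(pH, c: InhibitionConstants):
    """Two-sided pH limit function in [0, 1], equal to 1 at the pH optimum.

    Uses the empirical lower/upper-bound bell common in anaerobic-digestion
    models, rescaled by its value at the midpoint of the bounds so the
    contract "1 at the group optimum" holds exactly.
    """
    pH = np.asarray(pH, dtype=float)

    def _raw(x):
        return (1.0 + 2.0 * 10.0 ** (0.5 * (c.pH_LL - c.pH_UL))) / (
            1.0 + 10.0 ** (x - c.pH_UL) + 10.0 ** (c.pH_LL - x)
        )

    val = _raw(pH) / _raw(c.pH_opt)
    val = np.clip(val, 0.0, 1.0)
    return val if val.ndim else float(val)


def noncompetitive_inhibition(C, K_I):
    """I = 1 / (1 + C / K_I), clipped to [0, 1]."""
    C = np.maximum(np.asarray(C, dtype=float), 0.0)
    val = 1.0 / (1.0 + C / K_I)
    val = np.clip(val, 0.0, 1.0)
    return val if val.ndim else float(val)


def inhibition_product(pH, C_NH3, C_NH4, C_H2S, group: MicrobialGroup):
    """Product of the four inhibition factors for one group, in [0, 1].

    Factors: pH limit function, and noncompetitive terms for free ammonia,
    ammonium, and unionized hydrogen sulfide (concentrations in g per kg
    slurry).
    """
    c = group.inhibition
    val = (
        ph_inhibition(pH, c)
        * noncompetitive_inhibition(C_NH3, c.K_I_NH3)
        * noncompetitive_inhibition(C_NH4, c.K_I_NH4)
        * noncompetitive_inhibition(C_H2S, c.K_I_H2S)
    )
    val = np.clip(val, 0.0, 1.0)
    return val if np.ndim(val) else float(val)


# ------------------------------------------------------------------
# Chemical speciation.  pKa laws are van 't Hoff-type in the absolute
# temperature; the coefficients are module-level so a scenario config can
# override them.

#: NH4+ acid dissociation: pKa(T) = A + B / T_K (Emerson-type; 9.25 at 25 degC).
NH4_PKA_A = 0.09018
NH4_PKA_B = 2729.92

#: H2S first dissociation: pKa1(T) = A + B / T_K (about 7.09 at 25 degC).
H2S_PKA1_A = 2.527
H2S_PKA1_B = 1359.96


def nh4_pka(T):
    """pKa of NH4+ at slurry temperature T (degC)."""
    T_K = np.asarray(T, dtype=float) + 273.15
    val = NH4_PKA_A + NH4_PKA_B / T_K
    return val if val.ndim else float(val)


def h2s_pka1(T):
    """First pKa of H2S at slurry temperature T (degC)."""
    T_K = np.asarray(T, dtype=float) + 273.15
    val = H2S_PKA1_A + H2S_PKA1_B / T_K
    return val if val.ndim else float(val)


def speciate_tan(TAN, pH, T):
    """Split total ammoniacal N into (NH3, NH4+), both in the input's units.

    The free-ammonia fraction is 1 / (1 + 10^(pKa(T) - pH)).  Conserves the
    total exactly.
    """
    TAN = np.asarray(TAN, dtype=float)
    if np.any(TAN < 0):
        raise ValueError("TAN must be >= 0")
    f_nh3 = 1.0 / (1.0 + 10.0 ** (nh4_pka(T) - np.asarray(pH, dtype=float)))
    nh3 = TAN * f_nh3
    nh4 = TAN - nh3
    if np.ndim(nh3):
        return nh3, nh4
    return float(nh3), float(nh4)


def speciate_sulfide(S_total, pH, T, slurry_mass):
    """Unionized aqueous H2S concentration, g S per kg slurry.

    ``S_total`` is the total dissolved sulfide pool (g S); the unionized
    fraction is 1 / (1 + 10^(pH - pKa1(T))).
    """
    S_total = np.asarray(S_total, dtype=float)
    if np.any(S_total < 0):
        raise ValueError("sulfide pool must be >= 0")
    if np.any(np.asarray(slurry_mass) <= 0):
        raise ZeroDivisionError("slurry mass must be positive to form a concentration")
    f_h2s = 1.0 / (1.0 + 10.0 ** (np.asarray(pH, dtype=float) - h2s_pka1(T)))
    conc = S_total * f_h2s / np.asarray(slurry_mass, dtype=float)
    return conc if np.ndim(conc) else float(conc)
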