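"""Productivity coefficients, VS/COD conversion, and COD-balance auditing.

Chemical oxygen demand (COD) is the model's conserved currency: 1 g of CH4
carries 4 g COD, 1 g of sulfide-S carries 2 g COD, and microbial biomass is
tracked directly in COD units.  The coefficients here translate substrate
turnover (g COD-S) into gas masses (g CH4, g CO2) and sulfur transfer.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "COD_PER_G_CH4",
    "COD_PER_G_SULFIDE_S",
    "Productivities",
    "VSConversion",
    "methane_productivity",
    "co2_productivities",
    "default_productivities",
    "sulfur_transfer_coefficient",
    "vs_to_degradable_cod",
    "cod_balance",
]

#: g COD per g CH4 (CH4 + 2 O2 -> CO2 + 2 H2O; 64 g O2 per 16 g CH4).
COD_PER_G_CH4 = 4.0
#: g COD per g sulfide-S (H2S + 2 O2 -> SO4^2- + 2 H+; 64 g O2 per 32 g S).
COD_PER_G_SULFIDE_S = 2.0

# Molar bookkeeping for the acetate-based defaults: 1 mol acetate = 64 g COD,
# degrading to 1 mol CH4 + 1 mol CO2; with sulfate, to 2 mol CO2.
_G_COD_PER_MOL_ACETATE = 64.0
_G_CO2_PER_MOL = 44.0
_G_CH4_PER_MOL = 16.0


@dataclass(frozen=True)
class Productivities:
    """Gas-production and sulfur-transfer coefficients per g COD-S turned over.

    * ``P_CH4`` — g CH4 per g COD-S consumed by methanogens.
    * ``P_CO2_anaer`` — g CO2 per g COD-S consumed by methanogens; lumps
      fermentation and methanogenesis, so it is only accurate at steady
      state or as a cumulative response, not during VFA accumulation.
    * ``P_CO2_sr`` — g CO2 per g COD-S consumed by sulfate reducers.
    * ``P_CO2_aer`` — g CO2 per g COD-S respired at the surface.
    * ``f_CODS_sulfur`` — g sulfate-S reduced (and sulfide-S produced) per
      g COD-S consumed by sulfate reducers.
    """

    P_CH4: float
    P_CO2_anaer: float
    P_CO2_sr: float
    P_CO2_aer: float
    f_CODS_sulfur: float

    def __post_init__(self) -> None:
        for name in ("P_CH4", "P_CO2_anaer", "P_CO2_sr", "P_CO2_aer", "f_CODS_sulfur"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.P_CH4 > 0.25 + 1e-9:
            raise ValueError(
                "P_CH4 cannot exceed 0.25 g CH4 per g COD-S (COD closure)"
            )


@dataclass(frozen=True)
class VSConversion:
    """Conversion from volatile solids to degradable particulate COD."""

    f_degradable: float = 0.42   # degradable fraction of VS in cattle slurry
    cod_per_vs: float = 1.42     # g COD per g VS

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_degradable <= 1.0:
            raise ValueError("f_degradable must lie in [0, 1]")
        if self.cod_per_vs <= 0:
            raise ValueError("cod_per_vs must be positive")


def methane_productivity(Y: float) -> float:
    """P_CH4 = (1 - Y) / 4 g CH4 per g COD-S.

    Substrate COD not incorporated into biomass (yield ``Y``) leaves as CH4,
    and CH4 carries 4 g COD per g, so COD closes exactly: Y + 4 P_CH4 = 1.
    """
    if not 0 < Y < 1:
        raise ValueError(f"yield must lie in (0, 1), got {Y}")
    return (1.0 - Y) / COD_PER_G_CH4


def co2_productivities(
    Y: float,
    Y_sr: float | None = None,
    Y_aer: float = 0.0,
) -> tuple[float, float, float]:
    """(P_CO2_anaer, P_CO2_sr, P_CO2_aer) from acetate-based stoichiometry.

    Acetate (64 g COD per mol) ferments/methanizes to 1 mol CH4 + 1 mol CO2,
    is oxidized by sulfate to 2 mol CO2, and combusts aerobically to 2 mol
    CO2; each pathway emits CO2 only from the substrate fraction not
    incorporated into biomass.  All three are config-overridable constants in
    a scenario; this function supplies the defaults.
    """
    if not 0 <= Y <= 1:
        raise ValueError("yield must lie in [0, 1]")
    if Y_sr is None:
        Y_sr = Y
    p_anaer = (1.0 - Y) * _G_CO2_PER_MOL / _G_COD_PER_MOL_ACETATE
    p_sr = (1.0 - Y_sr) * 2.0 * _G_CO2_PER_MOL / _G_COD_PER_MOL_ACETATE
    p_aer = (1.0 - Y_aer) * 2.0 * _G_CO2_PER_MOL / _G_COD_PER_MOL_ACETATE
    return p_anaer, p_sr, p_aer


def sulfur_transfer_coefficient(Y_sr: float) -> float:
    """Default f_COD-S,sulfur: g sulfate-S reduced per g COD-S consumed.

    Electron balance: COD not incorporated into sulfate-reducer biomass is
    transferred to sulfide, which carries 2 g COD per g S, giving
    (1 - Y_sr) / 2.  With Y_sr -> 0 this is the pure acetate/sulfate value
    of 0.5 g S per g COD.
    """
    if not 0 <= Y_sr <= 1:
        raise ValueError("Y_sr must lie in [0, 1]")
    return (1.0 - Y_sr) / COD_PER_G_SULFIDE_S


def default_productivities(Y: float = 0.05, Y_sr: float = 0.077) -> Productivities:
    """Productivity set derived from the default yields."""
    p_anaer, p_sr, p_aer = co2_productivities(Y, Y_sr)
    return Productivities(
        P_CH4=methane_productivity(Y),
        P_CO2_anaer=p_anaer,
        P_CO2_sr=p_sr,
        P_CO2_aer=p_aer,
        f_CODS_sulfur=sulfur_transfer_coefficient(Y_sr),
    )


def vs_to_degradable_cod(VS: float, c: VSConversion = VSConversion()) -> float:
    """Degradable particulate COD (g) from a VS mass (g)."""
    if VS < 0:
        raise ValueError("VS must be >= 0")
    return VS * c.f_degradable * c.cod_per_vs


def cod_balance(trajectory) -> float:
    """Relative COD-balance residual of a simulated trajectory.

    Audits

        COD_initial + COD_inflow  =  COD_stored + COD_removed
                                     + 4 * CH4_emitted + COD_respired
                                     + 2 * sulfide-S emitted

    where stored and removed COD count particulate substrate, VFA, biomass,
    and dissolved sulfide at 2 g COD per g S.  Returns
    |imbalance| / (COD_initial + COD_inflow).  The residual should sit at
    solver precision for any simulation, with or without emptying events.
    """
    initial = trajectory.initial_cod
    inflow = trajectory.cod_inflow_cum
    stored = trajectory.stored_cod_final
    removed = trajectory.cod_removed_cum
    ch4 = trajectory.summary["CH4_cum"]
    respired = trajectory.cod_respired_cum
    h2s = trajectory.summary["H2S_emitted_cum"]
    total_in = initial + inflow
    if total_in <= 0:
        return 0.0
    imbalance = total_in - stored - removed - COD_PER_G_CH4 * ch4 \
        - respired - COD_PER_G_SULFIDE_S * h2s
    return abs(imbalance) / total_in
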