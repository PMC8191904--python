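"""The shipped default parameter set ("builtin").

Five methanogen groups (m1-m5) spanning psychrophilic to thermophilic
temperature responses, plus one optional mesophilic sulfate reducer (sr1).
Temperature optima follow the species each group emulates:

* m1 — *Methanolobus psychrophilus*, cold-adapted;
* m2 — *Methanosarcina soligelidi*, cool-temperate;
* m3 — *Methanobrevibacter*/*Methanocorpusculum*, mesophilic (gut-derived,
  seeded an order of magnitude more densely in fresh slurry than the rest:
  0.01 vs 0.001 g COD-B per kg);
* m4 — no named species; T_opt midway between m3 and m5;
* m5 — *Methanosarcina thermophila*, thermophilic.

Each group's q_max,opt follows the linear rule (0 at 0 degC to 8 g COD-S
g COD-B^-1 d^-1 at 40 degC); the sulfate reducer gets a modest advantage in
both q_max,opt and yield, reflecting the typical kinetic edge of acetotrophic
sulfate reducers over acetoclastic methanogens.

Every entry carries a provenance tag: ``fixed`` values are constants of the
default model formulation; ``placeholder`` values are literature-informed
choices where no published default exists, all overridable through the
scenario config.
"""

from __future__ import annotations

from .kinetics import (
    CardinalParams,
    InhibitionConstants,
    KSTemperatureParams,
    MicrobialGroup,
    qmax_opt_from_linear_rule,
)
from .reactor import InfluentComposition, TransferParams
from .stoichiometry import default_productivities

__all__ = [
    "DEFAULT_Y",
    "DEFAULT_Y_SR",
    "DEFAULT_KD",
    "default_hydrolysis",
    "default_ks_params",
    "default_methanogens",
    "default_sulfate_reducer",
    "default_influent",
    "default_transfer",
    "default_productivity_set",
    "CARDINAL_TEMPERATURES",
    "INFLUENT_BIOMASS",
    "PROVENANCE",
]

DEFAULT_Y = 0.05         # g COD-B / g COD-S, all methanogen groups
DEFAULT_Y_SR = 0.077     # sulfate reducer yield
DEFAULT_KD = 0.02        # d^-1, first-order biomass decay

#: (T_min, T_opt, T_max) per group, degC.
CARDINAL_TEMPERATURES = {
    "m1": (0.0, 18.0, 25.0),
    "m2": (0.0, 28.0, 38.0),
    "m3": (10.0, 37.0, 45.0),
    "m4": (12.5, 43.5, 52.0),   # T_opt = (37 + 50)/2
    "m5": (15.0, 50.0, 58.0),
    "sr1": (10.0, 38.0, 46.0),
}

#: Influent active-biomass seeding, g COD-B per kg slurry.
INFLUENT_BIOMASS = {
    "m1": 0.001, "m2": 0.001, "m3": 0.01, "m4": 0.001, "m5": 0.001,
    "sr1": 0.001,
}

#: q_max,opt multiplier of the sulfate reducer relative to the linear rule.
SR_QMAX_FACTOR = 1.2

PROVENANCE = {
    "Y": "fixed", "Y_sr": "placeholder", "k_d": "placeholder",
    "alpha_opt": "fixed", "alpha_cardinal": "fixed",
    "qmax_rule": "fixed", "influent_biomass": "fixed",
    "cardinal_temperatures": "placeholder", "ks_params": "placeholder",
    "inhibition_constants": "placeholder", "influent_chemistry": "placeholder",
    "transfer": "placeholder", "management": "fixed",
    "vs_conversion": "fixed",
}


def default_hydrolysis() -> CardinalParams:
    """Hydrolysis rate constant alpha: CTM1 with alpha_opt = 0.02 d^-1 at
    T_opt = 50 degC, T_min = 0, T_max = 60 degC."""
    return CardinalParams(T_min=0.0, T_opt=50.0, T_max=60.0, rate_opt=0.02)


def default_ks_params() -> KSTemperatureParams:
    """Shared K_S(T) law: 1.0 g COD-S/kg at 0 degC declining 5% per degC."""
    return KSTemperatureParams(k1=1.0, k2=0.05)


def _group(name: str, *, sr: bool = False, X_init: float = 0.0) -> MicrobialGroup:
    t_min, t_opt, t_max = CARDINAL_TEMPERATURES[name]
    q_opt = qmax_opt_from_linear_rule(t_opt)
    if sr:
        q_opt *= SR_QMAX_FACTOR
    inhib = InhibitionConstants(pH_LL=5.0 if sr else 6.0, pH_UL=8.5)
    return MicrobialGroup(
        id=name,
        cardinal=CardinalParams(t_min, t_opt, t_max, q_opt),
        Y=DEFAULT_Y_SR if sr else DEFAULT_Y,
        k_d=DEFAULT_KD,
        KS_coef=1.0,
        inhibition=inhib,
        C_X_in=INFLUENT_BIOMASS[name],
        X_init=X_init,
        is_sulfate_reducer=sr,
    )


def default_methanogens() -> list[MicrobialGroup]:
    """The default five-group methanogen community (no sulfate reducer)."""
    return [_group(n) for n in ("m1", "m2", "m3", "m4", "m5")]


def default_sulfate_reducer() -> MicrobialGroup:
    """The optional sr1 group (enable for acidification/sulfate scenarios)."""
    return _group("sr1", sr=True)


def default_influent() -> InfluentComposition:
    return InfluentComposition()


def default_transfer() -> TransferParams:
    return TransferParams()


def default_productivity_set():
    return default_productivities(Y=DEFAULT_Y, Y_sr=DEFAULT_Y_SR)
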