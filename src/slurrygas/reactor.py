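"""Continuous reactor dynamics: state vector, Petersen-matrix RHS, gas transfer.

The slurry store is a semi-batch reactor.  Eight processes act on the state:

1. hydrolysis/fermentation of degradable particulate COD (S_p) to VFA,
2. VFA uptake by each methanogen group (Monod, with inhibition),
3. VFA uptake by the sulfate reducer (double Monod on VFA and sulfate),
4. aerobic respiration of S_p at the slurry surface (O2-transfer limited),
5. H2S volatilization from the surface,
6./7. first-order biomass decay, recycled into S_p,
8. slurry inflow at rate F_in with fixed influent concentrations.

Slurry removal is instantaneous and handled by the management module, not
here.  All masses are absolute pools (g, kg for slurry mass); Monod terms use
concentrations formed by dividing pools by the current slurry mass.

The state vector layout is ``[M_m, S_p, VFA, SO4, sulfide, TAN, X_1..X_k,
CH4_cum, CO2_cum, H2S_emitted_cum, <4 audit accumulators>]``; the audit
accumulators integrate inflow COD, respired COD, inflow sulfur and inflow TAN
so mass balances can be closed to solver precision after the fact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import kinetics
from .kinetics import KSTemperatureParams, MicrobialGroup, CardinalParams
from .stoichiometry import COD_PER_G_SULFIDE_S, Productivities

__all__ = [
    "SlurryState",
    "InfluentComposition",
    "TransferParams",
    "surface_respiration",
    "h2s_emission_rate",
    "ReactorModel",
]


@dataclass
class SlurryState:
    """Instantaneous reactor state (absolute pools).

    ``X`` holds one biomass entry per microbial group, in scenario group
    order.  Cumulative counters are global (never reset by removal events).
    """

    M_m: float                      # kg slurry
    S_p: float                      # g COD-S, degradable particulate
    VFA: float                      # g COD-S
    SO4: float = 0.0                # g SO4-S
    sulfide: float = 0.0            # g S, dissolved
    TAN: float = 0.0                # g N
    X: np.ndarray = field(default_factory=lambda: np.zeros(0))
    CH4_cum: float = 0.0            # g CH4
    CO2_cum: float = 0.0            # g CO2
    H2S_emitted_cum: float = 0.0    # g S

    def validate(self) -> None:
        pools = [self.M_m, self.S_p, self.VFA, self.SO4, self.sulfide, self.TAN]
        if any(p < 0 for p in pools) or np.any(self.X < 0):
            raise ValueError("state pools must be nonnegative")


@dataclass(frozen=True)
class InfluentComposition:
    """Concentrations in the produced (influent) slurry, per kg of slurry."""

    C_Sp_in: float = 47.7       # g COD-S/kg (80 g VS/kg * 0.42 degradable * 1.42)
    C_VFA_in: float = 2.0       # g COD-S/kg
    C_SO4_in: float = 0.2       # g SO4-S/kg
    C_H2S_in: float = 0.0       # g S/kg
    C_TAN_in: float = 2.0       # g N/kg

    def __post_init__(self) -> None:
        for name in ("C_Sp_in", "C_VFA_in", "C_SO4_in", "C_H2S_in", "C_TAN_in"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TransferParams:
    """Air-slurry transfer parameters for surface respiration and H2S loss.

    Respiration is O2-transfer limited: the flux is kL_O2 * area * C_O2,sat
    with C_O2,sat = pO2 / kH_O2, independent of the bulk substrate level.
    H2S emission is kL_H2S * area * C_H2S with C_H2S the unionized aqueous
    concentration (g S per kg slurry); kL_H2S therefore carries kg m^-2 d^-1
    (a 1 cm stagnant film with D_H2S ~ 1.4e-4 m^2 d^-1 and unit slurry
    density gives ~14).
    """

    area: float = 17.0          # m^2
    kL_O2: float = 0.2          # m d^-1
    kH_O2: float = 0.0231       # atm m^3 g^-1  (0.208/kH = 9 g O2 m^-3 at ~20 degC)
    kL_H2S: float = 14.0        # kg m^-2 d^-1
    pO2: float = 0.208          # atm, atmospheric mole fraction
    resp_eps: float = 1.0       # g COD-S, smooth gate so respiration stops at S_p=0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("area must be positive")
        for name in ("kL_O2", "kH_O2", "kL_H2S", "pO2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def surface_respiration(tp: TransferParams) -> float:
    """O2-transfer-limited surface respiration rate, g COD-S d^-1 (ungated)."""
    if tp.kH_O2 == 0:
        return 0.0
    return tp.kL_O2 * tp.area * (tp.pO2 / tp.kH_O2 - 0.0)


def h2s_emission_rate(tp: TransferParams, C_H2S: float) -> float:
    """H2S volatilization rate, g S d^-1, linear in area and concentration."""
    return tp.kL_H2S * tp.area * (max(C_H2S, 0.0) - 0.0)


class ReactorModel:
    """Compiled right-hand side for a fixed set of microbial groups.

    Precomputes per-group parameter arrays so the RHS is pure vectorized
    numpy; temperature, pH and inflow rate are supplied per evaluation by
    the caller (the simulator interpolates the forcings).
    """

    N_FIXED = 6       # M_m, S_p, VFA, SO4, sulfide, TAN
    N_TAIL = 7        # CH4, CO2, H2S_em, COD_in, COD_resp, S_in, TAN_in

    def __init__(
        self,
        groups: list[MicrobialGroup],
        hydrolysis: CardinalParams,
        ks_params: KSTemperatureParams,
        influent: InfluentComposition,
        transfer: TransferParams,
        productivities: Productivities,
    ):
        if not groups:
            raise ValueError("at least one microbial group is required")
        sr_flags = [g.is_sulfate_reducer for g in groups]
        if sum(sr_flags) > 1:
            raise ValueError("at most one sulfate-reducer group is supported")
        self.groups = list(groups)
        self.hydrolysis = hydrolysis
        self.ks_params = ks_params
        self.influent = influent
        self.transfer = transfer
        self.prod = productivities

        self.k = len(groups)
        self.is_sr = np.array(sr_flags, dtype=bool)
        self.T_min = np.array([g.cardinal.T_min for g in groups])
        self.T_opt = np.array([g.cardinal.T_opt for g in groups])
        self.T_max = np.array([g.cardinal.T_max for g in groups])
        self.q_opt = np.array([g.cardinal.rate_opt for g in groups])
        self.Y = np.array([g.Y for g in groups])
        self.k_d = np.array([g.k_d for g in groups])
        self.KS_coef = np.array([g.KS_coef for g in groups])
        self.KS_SO4 = np.array([g.KS_SO4 for g in groups])
        self.C_X_in = np.array([g.C_X_in for g in groups])
        self.pH_LL = np.array([g.inhibition.pH_LL for g in groups])
        self.pH_UL = np.array([g.inhibition.pH_UL for g in groups])
        self.KI_NH3 = np.array([g.inhibition.K_I_NH3 for g in groups])
        self.KI_NH4 = np.array([g.inhibition.K_I_NH4 for g in groups])
        self.KI_H2S = np.array([g.inhibition.K_I_H2S for g in groups])
        # pH bell normalisation so each group's factor is 1 at its optimum
        self._ph_peak = (1.0 + 2.0 * 10.0 ** (0.5 * (self.pH_LL - self.pH_UL))) / (
            1.0
            + 10.0 ** (0.5 * (self.pH_LL + self.pH_UL) - self.pH_UL)
            + 10.0 ** (self.pH_LL - 0.5 * (self.pH_LL + self.pH_UL))
        )
        self.n_state = self.N_FIXED + self.k + self.N_TAIL

    # -- state vector helpers -------------------------------------------------

    def pack(self, s: SlurryState) -> np.ndarray:
        y = np.zeros(self.n_state)
        y[0:6] = [s.M_m, s.S_p, s.VFA, s.SO4, s.sulfide, s.TAN]
        y[6:6 + self.k] = s.X
        y[6 + self.k:9 + self.k] = [s.CH4_cum, s.CO2_cum, s.H2S_emitted_cum]
        return y

    def unpack(self, y: np.ndarray) -> SlurryState:
        k = self.k
        return SlurryState(
            M_m=float(y[0]), S_p=float(y[1]), VFA=float(y[2]), SO4=float(y[3]),
            sulfide=float(y[4]), TAN=float(y[5]), X=np.array(y[6:6 + k]),
            CH4_cum=float(y[6 + k]), CO2_cum=float(y[7 + k]),
            H2S_emitted_cum=float(y[8 + k]),
        )

    def initial_vector(self, s: SlurryState) -> np.ndarray:
        s.validate()
        if len(s.X) != self.k:
            raise ValueError(f"state carries {len(s.X)} biomass pools, model has {self.k}")
        return self.pack(s)

    # -- kinetics -------------------------------------------------------------

    def _ctm1(self, T: float) -> np.ndarray:
        """Vectorized CTM1 over all groups at scalar temperature T."""
        num = (T - self.T_max) * (T - self.T_min) ** 2
        den = (self.T_opt - self.T_min) * (
            (self.T_opt - self.T_min) * (T - self.T_opt)
            - (self.T_opt - self.T_max) * (self.T_opt + self.T_min - 2.0 * T)
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(den != 0.0, self.q_opt * num / np.where(den != 0.0, den, 1.0), 0.0)
        q[(T <= self.T_min) | (T >= self.T_max)] = 0.0
        return np.maximum(q, 0.0)

    def _inhibition(self, pH: float, C_NH3: float, C_NH4: float, C_H2S: float) -> np.ndarray:
        """Per-group product of the 4 inhibition factors (vectorized)."""
        raw = (1.0 + 2.0 * 10.0 ** (0.5 * (self.pH_LL - self.pH_UL))) / (
            1.0 + 10.0 ** (pH - self.pH_UL) + 10.0 ** (self.pH_LL - pH)
        )
        I = np.clip(raw / self._ph_peak, 0.0, 1.0)
        I = I / (1.0 + C_NH3 / self.KI_NH3)
        I = I / (1.0 + C_NH4 / self.KI_NH4)
        I = I / (1.0 + C_H2S / self.KI_H2S)
        return np.clip(I, 0.0, 1.0)

    def process_rates(self, y: np.ndarray, T: float, pH: float) -> dict:
        """Instantaneous process rates at state ``y`` (for logging/audit).

        Returns hydrolysis (g COD d^-1), per-group uptake magnitudes
        (g COD d^-1), respiration (g COD d^-1), H2S emission (g S d^-1),
        per-group decay (g COD d^-1), and the per-group inhibition products.
        """
        M_m = max(float(y[0]), 1e-12)
        S_p = max(float(y[1]), 0.0)
        VFA = max(float(y[2]), 0.0)
        SO4 = max(float(y[3]), 0.0)
        sulfide = max(float(y[4]), 0.0)
        TAN = max(float(y[5]), 0.0)
        X = np.maximum(y[6:6 + self.k], 0.0)

        C_VFA = VFA / M_m
        C_SO4 = SO4 / M_m
        f_nh3 = 1.0 / (1.0 + 10.0 ** (kinetics.nh4_pka(T) - pH))
        C_NH3 = TAN * f_nh3 / M_m
        C_NH4 = TAN * (1.0 - f_nh3) / M_m
        f_h2s = 1.0 / (1.0 + 10.0 ** (pH - kinetics.h2s_pka1(T)))
        C_H2S = sulfide * f_h2s / M_m

        alpha = kinetics.cardinal_rate(T, self.hydrolysis)
        q_max = self._ctm1(T)
        K_S = self.KS_coef * self.ks_params.k1 * np.exp(-self.ks_params.k2 * T)
        I = self._inhibition(pH, C_NH3, C_NH4, C_H2S)

        uptake = q_max * C_VFA / (K_S + C_VFA) * X * I
        uptake = np.where(self.is_sr, uptake * C_SO4 / (self.KS_SO4 + C_SO4), uptake)

        R = surface_respiration(self.transfer) * S_p / (S_p + self.transfer.resp_eps)
        E_h2s = h2s_emission_rate(self.transfer, C_H2S)
        decay = self.k_d * X

        return {
            "hydrolysis": alpha * S_p,
            "uptake": uptake,
            "respiration": R,
            "h2s_emission": E_h2s,
            "decay": decay,
            "inhibition": I,
            "q_max": q_max,
            "K_S": K_S,
            "C_VFA": C_VFA,
            "C_H2S": C_H2S,
            "C_NH3": C_NH3,
        }

    def rhs(self, t: float, y: np.ndarray, T: float, pH: float, F_in: float) -> np.ndarray:
        """Time derivative of the full state vector at forcings (T, pH, F_in)."""
        r = self.process_rates(y, T, pH)
        inf = self.influent
        prod = self.prod
        k = self.k

        uptake = r["uptake"]
        meth_uptake = np.where(self.is_sr, 0.0, uptake)
        sr_uptake = float(np.sum(np.where(self.is_sr, uptake, 0.0)))
        sum_meth = float(np.sum(meth_uptake))
        decay_total = float(np.sum(r["decay"]))

        dy = np.zeros_like(y)
        dy[0] = F_in                                                   # M_m
        dy[1] = (-r["hydrolysis"] - r["respiration"] + decay_total
                 + F_in * inf.C_Sp_in)                                 # S_p
        dy[2] = (r["hydrolysis"] - sum_meth - sr_uptake
                 + F_in * inf.C_VFA_in)                                # VFA
        dy[3] = -prod.f_CODS_sulfur * sr_uptake + F_in * inf.C_SO4_in  # SO4
        dy[4] = (prod.f_CODS_sulfur * sr_uptake - r["h2s_emission"]
                 + F_in * inf.C_H2S_in)                                # sulfide
        dy[5] = F_in * inf.C_TAN_in                                    # TAN
        dy[6:6 + k] = self.Y * uptake - r["decay"] + F_in * self.C_X_in
        dy[6 + k] = prod.P_CH4 * sum_meth                              # CH4
        dy[7 + k] = (prod.P_CO2_anaer * sum_meth + prod.P_CO2_sr * sr_uptake
                     + prod.P_CO2_aer * r["respiration"])              # CO2
        dy[8 + k] = r["h2s_emission"]                                  # H2S emitted
        # audit accumulators
        dy[9 + k] = F_in * (inf.C_Sp_in + inf.C_VFA_in
                            + float(np.sum(self.C_X_in))
                            + COD_PER_G_SULFIDE_S * inf.C_H2S_in)      # COD inflow
        dy[10 + k] = r["respiration"]                                  # COD respired
        dy[11 + k] = F_in * (inf.C_SO4_in + inf.C_H2S_in)              # S inflow
        dy[12 + k] = F_in * inf.C_TAN_in                               # TAN inflow
        return dy

    def stored_cod(self, y: np.ndarray) -> float:
        """COD held in the store: substrate + VFA + biomass + sulfide-COD."""
        k = self.k
        return float(
            y[1] + y[2] + np.sum(y[6:6 + k]) + COD_PER_G_SULFIDE_S * y[4]
        )
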