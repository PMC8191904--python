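"""Right-hand-side assembly, gas transfer, and conservation properties.

The RHS is cross-checked against a brute-force oracle that assembles the
eight processes one by one from the public kinetics functions and applies
the signed stoichiometry explicitly, pool by pool.
"""

import numpy as np
import pytest

import slurrygas as sg
from slurrygas import kinetics
from slurrygas.defaults import (
    default_hydrolysis,
    default_influent,
    default_ks_params,
    default_methanogens,
    default_productivity_set,
    default_sulfate_reducer,
    default_transfer,
)
from slurrygas.reactor import ReactorModel, TransferParams, h2s_emission_rate, surface_respiration
from slurrygas.stoichiometry import COD_PER_G_SULFIDE_S


def make_model(with_sr=True) -> ReactorModel:
    groups = default_methanogens()
    if with_sr:
        groups.append(default_sulfate_reducer())
    return ReactorModel(
        groups, default_hydrolysis(), default_ks_params(), default_influent(),
        default_transfer(), default_productivity_set(),
    )


def random_state(model: ReactorModel, rng) -> np.ndarray:
    y = np.zeros(model.n_state)
    y[0] = rng.uniform(1000.0, 30000.0)               # M_m
    y[1] = rng.uniform(0.0, 2e6)                      # S_p
    y[2] = rng.uniform(0.0, 2e5)                      # VFA
    y[3] = rng.uniform(0.0, 5e4)                      # SO4
    y[4] = rng.uniform(0.0, 1e3)                      # sulfide
    y[5] = rng.uniform(0.0, 1e5)                      # TAN
    y[6:6 + model.k] = rng.uniform(0.0, 5e3, model.k)
    return y


def oracle_rhs(model: ReactorModel, y, T, pH, F_in):
    """Brute-force Petersen assembly from the public kinetics functions."""
    g_list = model.groups
    inf, tp, prod = model.influent, model.transfer, model.prod
    M_m, S_p, VFA, SO4, sulfide, TAN = y[:6]
    X = y[6:6 + model.k]

    C_VFA, C_SO4 = VFA / M_m, SO4 / M_m
    NH3, NH4 = kinetics.speciate_tan(TAN, pH, T)
    C_H2S = kinetics.speciate_sulfide(sulfide, pH, T, M_m)

    alpha = kinetics.cardinal_rate(T, model.hydrolysis)
    r_hyd = alpha * S_p
    R = surface_respiration(tp) * S_p / (S_p + tp.resp_eps)
    E = h2s_emission_rate(tp, C_H2S)

    uptake, growth, decay = [], [], []
    for g, x in zip(g_list, X):
        q = kinetics.cardinal_rate(T, g.cardinal)
        ks = kinetics.ks_at_temperature(T, g.KS_coef, model.ks_params)
        I = kinetics.inhibition_product(pH, NH3 / M_m, NH4 / M_m, C_H2S, g)
        if g.is_sulfate_reducer:
            r = kinetics.sulfate_reduction_rate(C_VFA, C_SO4, ks, g.KS_SO4, q, x, I)
        else:
            r = kinetics.methanogen_uptake_rate(C_VFA, ks, q, x, I)
        uptake.append(r)
        growth.append(g.Y * r)
        decay.append(g.k_d * x)
    uptake, growth, decay = map(np.array, (uptake, growth, decay))
    sr = np.array([g.is_sulfate_reducer for g in g_list])
    r_sr = float(uptake[sr].sum())
    r_meth = float(uptake[~sr].sum())

    dy = np.zeros_like(y)
    dy[0] = F_in
    dy[1] = -r_hyd - R + decay.sum() + F_in * inf.C_Sp_in
    dy[2] = r_hyd - r_meth - r_sr + F_in * inf.C_VFA_in
    dy[3] = -prod.f_CODS_sulfur * r_sr + F_in * inf.C_SO4_in
    dy[4] = prod.f_CODS_sulfur * r_sr - E + F_in * inf.C_H2S_in
    dy[5] = F_in * inf.C_TAN_in
    dy[6:6 + model.k] = growth - decay + F_in * model.C_X_in
    dy[6 + model.k] = prod.P_CH4 * r_meth
    dy[7 + model.k] = (prod.P_CO2_anaer * r_meth + prod.P_CO2_sr * r_sr
                       + prod.P_CO2_aer * R)
    dy[8 + model.k] = E
    return dy[:9 + model.k]


class TestRHSAgainstPetersenOracle:
    def test_random_states_agree(self, rng):
        model = make_model(with_sr=True)
        for _ in range(25):
            y = random_state(model, rng)
            T = rng.uniform(2.0, 45.0)
            pH = rng.uniform(5.0, 8.5)
            F_in = rng.uniform(0.0, 2000.0)
            got = model.rhs(0.0, y, T, pH, F_in)[:9 + model.k]
            want = oracle_rhs(model, y, T, pH, F_in)
            np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12)

    def test_cod_conserving(self, rng):
        """d(stored COD)/dt = inflow COD - 4*CH4 rate - respiration - sulfide loss."""
        model = make_model(with_sr=True)
        k = model.k
        for _ in range(25):
            y = random_state(model, rng)
            dy = model.rhs(0.0, y, rng.uniform(5, 45), rng.uniform(5.5, 8.5),
                           rng.uniform(0, 2000))
            d_stored = (dy[1] + dy[2] + dy[6:6 + k].sum()
                        + COD_PER_G_SULFIDE_S * dy[4])
            balance = (dy[9 + k]                       # inflow COD
                       - 4.0 * dy[6 + k]               # CH4 COD
                       - dy[10 + k]                    # respired COD
                       - COD_PER_G_SULFIDE_S * dy[8 + k])   # emitted H2S COD
            assert d_stored == pytest.approx(balance, rel=1e-9, abs=1e-9)

    def test_sulfur_conserving(self, rng):
        model = make_model(with_sr=True)
        k = model.k
        for _ in range(25):
            y = random_state(model, rng)
            dy = model.rhs(0.0, y, 25.0, 7.0, rng.uniform(0, 2000))
            # d(SO4 + sulfide + emitted)/dt equals the sulfur inflow rate
            assert dy[3] + dy[4] + dy[8 + k] == pytest.approx(dy[11 + k], abs=1e-9)

    def test_zero_rates_fixed_point(self):
        model = make_model()
        y = np.zeros(model.n_state)
        y[0] = 1000.0   # some slurry, but empty of substrate and biomass
        dy = model.rhs(0.0, y, 20.0, 7.0, 0.0)
        np.testing.assert_array_equal(dy, 0.0)

    def test_hydrolysis_is_internal_transfer(self):
        """Without microbes, inflow, or respiration, S_p + VFA is conserved."""
        model = ReactorModel(
            default_methanogens(), default_hydrolysis(), default_ks_params(),
            default_influent(), TransferParams(kL_O2=0.0),
            default_productivity_set(),
        )
        y = np.zeros(model.n_state)
        y[0], y[1], y[2] = 5000.0, 1e5, 1e3
        dy = model.rhs(0.0, y, 30.0, 7.0, 0.0)
        assert dy[1] + dy[2] == pytest.approx(0.0, abs=1e-12)
        assert dy[1] < 0 < dy[2]

    def test_ch4_rate_tracks_methanogen_uptake(self, rng):
        model = make_model(with_sr=True)
        y = random_state(model, rng)
        r = model.process_rates(y, 25.0, 7.0)
        meth = np.sum(np.where(model.is_sr, 0.0, r["uptake"]))
        dy = model.rhs(0.0, y, 25.0, 7.0, 500.0)
        assert dy[6 + model.k] == pytest.approx(model.prod.P_CH4 * meth)


class TestGasTransfer:
    def test_respiration_linear_in_area_and_zero_without_transfer(self):
        base = TransferParams(area=10.0)
        assert surface_respiration(TransferParams(kL_O2=0.0)) == 0.0
        doubled = TransferParams(area=20.0)
        assert surface_respiration(doubled) == pytest.approx(
            2.0 * surface_respiration(base))

    def test_respiration_negligible_for_deep_slurry(self):
        """At default parameters the O2 flux is tiny next to hydrolysis supply."""
        R = surface_respiration(TransferParams())
        influent_cod = 1000.0 * default_influent().C_Sp_in   # g/d into the store
        assert R < 0.01 * influent_cod

    def test_h2s_emission_linear(self):
        tp = TransferParams()
        assert h2s_emission_rate(tp, 0.0) == 0.0
        assert h2s_emission_rate(tp, 0.2) == pytest.approx(
            2.0 * h2s_emission_rate(tp, 0.1))
        assert h2s_emission_rate(TransferParams(area=34.0), 0.1) == pytest.approx(
            2.0 * h2s_emission_rate(TransferParams(area=17.0), 0.1))

    def test_emission_pools_monotone_in_simulation(self, short_scenario):
        traj = sg.simulate(short_scenario)
        for col in ("CH4_cum", "CO2_cum", "H2S_emitted_cum"):
            assert np.all(np.diff(traj.states[col]) >= -1e-9)
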