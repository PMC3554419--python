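"""Mass balances, chemostat contracts, carbon closure and off-gas rates."""

import numpy as np
import pytest

from glycotherm import ReactorConfig, carbon_balance_error, co2_offgas_rate
from glycotherm.reactor import (ReactorState, chemostat_steady_state,
                                initial_batch_state, reactor_derivative,
                                run_reactor)
from glycotherm.thermo import TemperatureProfile, apply_sensitivity, lts_profile


@pytest.fixture(scope="module")
def scale_funs(model, params):
    return apply_sensitivity(params, None, model.reaction_ids)


def scales_at(scale_funs, temp):
    return {rid: f(temp) for rid, f in scale_funs.items()}


class TestDerivative:
    def test_zero_biomass_closed_batch_is_static(self, model, batch_config,
                                                 scale_funs):
        state = ReactorState(n_i={"GLCo": 138.8, "ETOH": 0.0, "GLYC": 0.0,
                                  "CO2": 0.0}, n_x=0.0,
                             intracellular={s: 1.0 for s in model.dynamic_species})
        dn, dnx, _ = reactor_derivative(state, 0.0, model,
                                        scales_at(scale_funs, 30.0), batch_config)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in dn.values())
        assert dnx == 0.0

    def test_chemostat_steady_state_balances(self, model, chemostat_config,
                                             scale_funs):
        """At the solved steady state every extracellular balance closes:
        q_i·N_X = F·(C_out − C_in) for each species."""
        st = chemostat_steady_state(model, chemostat_config,
                                    scales_at(scale_funs, 30.0))
        dn, dnx, dc = reactor_derivative(st, 0.0, model,
                                         scales_at(scale_funs, 30.0),
                                         chemostat_config)
        assert abs(dnx) < 1e-6
        for sid, v in dn.items():
            if sid != "CO2":                     # CO2 column is cumulative
                assert v == pytest.approx(0.0, abs=1e-5)
        assert all(abs(v) < 1e-5 for v in dc.values())


class TestChemostat:
    def test_mu_equals_dilution_rate(self, model, chemostat_config, scale_funs):
        """The steady chemostat fixes the specific growth rate at D."""
        st = chemostat_steady_state(model, chemostat_config,
                                    scales_at(scale_funs, 30.0))
        conc = dict(st.intracellular)
        for sid in ("GLCo", "ETOH", "GLYC", "CO2"):
            conc[sid] = st.n_i.get(sid, 0.0) / chemostat_config.volume
        v = model.rates(conc, scales_at(scale_funs, 30.0))
        mu = chemostat_config.growth_rate(v["GLT"])
        assert abs(mu - chemostat_config.dilution_rate) <= 1e-4

    def test_dynamic_run_converges_to_mu_equals_d(self, model, chemostat_config,
                                                  scale_funs):
        st = chemostat_steady_state(model, chemostat_config,
                                    scales_at(scale_funs, 30.0))
        st.n_x *= 0.7                            # start away from steady state
        prof = TemperatureProfile("constant", constant_t=30.0)
        horizon = 5.0 / chemostat_config.dilution_rate
        traj = run_reactor(model, chemostat_config, prof, scale_funs,
                           (0.0, horizon), np.linspace(0, horizon, 100),
                           initial=st)
        assert traj.data["mu_h"].iloc[-1] == \
            pytest.approx(chemostat_config.dilution_rate, abs=1e-4)
        assert not traj.washout_flagged

    def test_zero_biomass_relaxes_to_feed(self, model, chemostat_config,
                                          scale_funs):
        st = ReactorState(n_i={"GLCo": 0.0, "ETOH": 0.0, "GLYC": 0.0, "CO2": 0.0},
                          n_x=0.0,
                          intracellular={s: 1e-3 for s in model.dynamic_species})
        prof = TemperatureProfile("constant", constant_t=30.0)
        traj = run_reactor(model, chemostat_config, prof, scale_funs,
                           (0.0, 250.0), np.linspace(0, 250, 50), initial=st)
        feed = chemostat_config.feed_concentrations["GLCo"]
        assert traj.data["GLCo"].iloc[-1] == pytest.approx(feed, rel=1e-2)
        assert traj.washout_flagged

    def test_residual_glucose_rises_as_temperature_falls(self, model,
                                                         chemostat_config,
                                                         scale_funs):
        """Cooling a glucose-limited chemostat lowers transport capacity, so
        residual glucose climbs monotonically on the down-ramp."""
        traj = run_reactor(model, chemostat_config, lts_profile(30.0, 12.0),
                           scale_funs, (0.0, 6.0), np.linspace(0, 6, 121))
        down = traj.data[traj.data["time_h"] <= 1.5]
        glc = down["GLCo"].to_numpy()
        assert np.all(np.diff(glc) >= -1e-9)
        assert glc[-1] > 5 * glc[0]


@pytest.fixture(scope="module")
def batch30(model, batch_config, scale_funs):
    prof = TemperatureProfile("constant", constant_t=30.0)
    return run_reactor(model, batch_config, prof, scale_funs, (0.0, 100.0),
                       np.linspace(0, 100, 2001), stop_on_glucose=30.0)


@pytest.fixture(scope="module")
def batch12(model, batch_config, scale_funs):
    prof = TemperatureProfile("constant", constant_t=12.0)
    return run_reactor(model, batch_config, prof, scale_funs, (0.0, 600.0),
                       np.linspace(0, 600, 4001), stop_on_glucose=30.0)


class TestBatch:
    def test_carbon_balance_closes(self, batch30, batch_config):
        """Glucose carbon consumed = ethanol + glycerol + CO2 + biomass +
        pool-change carbon, within 0.5% (evaporation off)."""
        assert carbon_balance_error(batch30, batch_config) < 0.005

    def test_homeostasis_across_temperature(self, batch30, batch12, model):
        """With identical sensitivities, intracellular pools at matched
        residual glucose are temperature-independent."""
        target = 120.0
        p30 = _at_glucose(batch30, target)
        p12 = _at_glucose(batch12, target)
        for met in model.dynamic_species:
            assert p12[met] == pytest.approx(p30[met], rel=1e-3)

    def test_specific_co2_ratio_is_capacity_ratio(self, batch30, batch12, params):
        from glycotherm.thermo import ratkowsky_scale
        expect = ratkowsky_scale(params, 30.0) / ratkowsky_scale(params, 12.0)
        ratio = _at_glucose(batch30, 120.0)["q_CO2"] / \
            _at_glucose(batch12, 120.0)["q_CO2"]
        assert ratio == pytest.approx(expect, rel=1e-3)


def _at_glucose(traj, target):
    d = traj.data
    g = d["GLCo"].to_numpy()
    k = int(np.nonzero(g <= target)[0][0])
    f = (g[k - 1] - target) / (g[k - 1] - g[k])
    return d.iloc[k - 1] + f * (d.iloc[k] - d.iloc[k - 1])


class TestOffGas:
    def test_zero_flux_zero_offgas(self):
        cfg = ReactorConfig(mode="batch")
        assert co2_offgas_rate({"q_CO2": 0.0, "biomass_gdw_l": 3.0}, cfg) == 0.0

    def test_linear_in_biomass(self):
        cfg = ReactorConfig(mode="batch")
        one = co2_offgas_rate({"q_CO2": 2.0, "biomass_gdw_l": 1.0}, cfg)
        two = co2_offgas_rate({"q_CO2": 2.0, "biomass_gdw_l": 2.0}, cfg)
        assert two == pytest.approx(2 * one)

    def test_steady_chemostat_offgas_constant(self, model, chemostat_config,
                                              scale_funs):
        prof = TemperatureProfile("constant", constant_t=30.0)
        traj = run_reactor(model, chemostat_config, prof, scale_funs,
                           (0.0, 20.0), np.linspace(0, 20, 40))
        rates = [co2_offgas_rate(row, chemostat_config)
                 for _, row in traj.data.iterrows()]
        assert np.ptp(rates) / np.mean(rates) < 1e-5


class TestBatchInitialState:
    def test_intracellular_at_excess_steady_state(self, model, batch_config,
                                                  scale_funs):
        st = initial_batch_state(model, batch_config, scales_at(scale_funs, 30.0))
        assert st.n_i["GLCo"] == pytest.approx(138.8 * batch_config.volume)
        assert all(c > 0 for c in st.intracellular.values())
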