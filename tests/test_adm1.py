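"""ADM1 core: charge-balance pH, conservation of the Petersen matrix,
kinetic limits and steady-state behaviour of the CSTR."""

import dataclasses

import numpy as np
import pytest

from codigest import feedstock as fs
from codigest.adm1 import (
    ADM1Model, ADM1Parameters, IDX, N_STATES, PROCESS_NAMES, STATE_NAMES,
    build_stoichiometry, simulate_cstr, solve_ph, yield_report,
)
from codigest.adm1.simulate import GasYields, SimulationResult


@pytest.fixture(scope="module")
def params():
    return ADM1Parameters()


def _random_states(n, seed=7):
    rng = np.random.default_rng(seed)
    states = rng.uniform(0.0, 5.0, size=(n, N_STATES))
    states[:, IDX["S_h2"]] *= 1e-6
    states[:, IDX["S_IC"]] = rng.uniform(0.0, 0.2, n)
    states[:, IDX["S_IN"]] = rng.uniform(0.0, 0.2, n)
    states[:, IDX["S_cat"]] = rng.uniform(0.0, 0.1, n)
    states[:, IDX["S_an"]] = rng.uniform(0.0, 0.1, n)
    return states


class TestPHSolver:
    def test_pure_water_neutral_at_25C(self):
        p = ADM1Parameters(T_op=298.15)
        state = np.zeros(N_STATES)
        ions = solve_ph(state, p)
        assert ions.pH == pytest.approx(7.0, abs=1e-6)

    def test_cations_raise_ph(self, params):
        state = np.zeros(N_STATES)
        state[IDX["S_IC"]] = 0.1
        phs = []
        for cat in (0.0, 0.02, 0.05, 0.09):
            state[IDX["S_cat"]] = cat
            phs.append(solve_ph(state, params).pH)
        assert all(a < b for a, b in zip(phs, phs[1:]))

    def test_residual_by_independent_substitution(self, params):
        """Re-evaluate the charge balance from the returned speciation."""
        for state in _random_states(300):
            ions = solve_ph(state, params)
            resid = (state[IDX["S_cat"]] + ions.S_nh4 + ions.S_H
                     - ions.S_hco3
                     - ions.S_ac_ion / 64.0 - ions.S_pro_ion / 112.0
                     - ions.S_bu_ion / 160.0 - ions.S_va_ion / 208.0
                     - state[IDX["S_an"]] - params.K_w / ions.S_H)
            assert abs(resid) < 1e-12

    def test_speciation_consistent_with_equilibria(self, params):
        state = _random_states(1)[0]
        ions = solve_ph(state, params)
        h = ions.S_H
        assert ions.S_nh3 * h == pytest.approx(ions.S_nh4 * params.K_a_IN,
                                               rel=1e-10)
        assert ions.S_hco3 * h == pytest.approx(ions.S_co2 * params.K_a_co2,
                                                rel=1e-10)


def _weights(params, partition):
    """Independently reconstructed COD / N / C content vectors."""
    p = params
    cod = np.zeros(len(STATE_NAMES))
    for n in ("S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac",
              "S_h2", "S_ch4", "S_I", "X_c", "X_ch", "X_pr", "X_li",
              "X_su", "X_aa", "X_fa", "X_c4", "X_pro", "X_ac", "X_h2", "X_I"):
        cod[IDX[n]] = 1.0
    nit = np.zeros(len(STATE_NAMES))
    nit[IDX["S_aa"]] = nit[IDX["X_pr"]] = p.N_aa
    nit[IDX["S_I"]] = nit[IDX["X_I"]] = p.N_I
    for g in ("su", "aa", "fa", "c4", "pro", "ac", "h2"):
        nit[IDX[f"X_{g}"]] = p.N_bac
    nit[IDX["X_c"]] = (partition.f_P_xc * p.N_aa + partition.f_I_xc * p.N_I)
    nit[IDX["S_IN"]] = 1.0
    return cod, nit


class TestStoichiometry:
    def test_cod_conserved_per_process(self, params, manure):
        part = fs.disintegration_partition(manure)
        nu = build_stoichiometry(params, part)
        cod, _ = _weights(params, part)
        assert np.max(np.abs(nu @ cod[:26])) < 1e-9

    def test_nitrogen_conserved_per_process(self, params, prairie):
        part = fs.disintegration_partition(prairie)
        nu = build_stoichiometry(params, part)
        _, nit = _weights(params, part)
        assert np.max(np.abs(nu @ nit[:26])) < 1e-9

    def test_balances_on_random_states(self, params, manure, prairie):
        """COD- and N-weighted biochemical derivatives vanish at 10^3 states."""
        inf = fs.blend_influent(prairie, manure, 0.0)
        model = ADM1Model(inf, params)
        cod, nit = _weights(params, inf.partition)
        for state in _random_states(1000, seed=11):
            rho, _ = model.process_rates(state)
            dy = model.nu.T @ rho
            assert abs(dy @ cod[:26]) < 1e-9 * max(np.sum(np.abs(dy)), 1.0)
            assert abs(dy @ nit[:26]) < 1e-9 * max(np.sum(np.abs(dy)), 1.0)

    def test_bad_partition_rejected(self, params):
        part = fs.DisintegrationPartition(d=0.5, f_Ch_xc=0.25, f_L_xc=0.25,
                                          f_P_xc=0.25, f_I_xc=0.25)
        with pytest.raises(ValueError, match="sum"):
            build_stoichiometry(params, part, f_sI=0.1)


class TestKinetics:
    def _model(self, manure, prairie, params):
        return ADM1Model(fs.blend_influent(prairie, manure, 0.0), params)

    def test_zero_biomass_zero_uptake(self, params, manure, prairie):
        model = self._model(manure, prairie, params)
        state = np.zeros(N_STATES)
        for n in ("S_su", "S_aa", "S_fa", "S_va", "S_bu", "S_pro", "S_ac"):
            state[IDX[n]] = 2.0
        state[IDX["S_IN"]] = 0.1
        rho, _ = model.process_rates(state)
        uptakes = slice(PROCESS_NAMES.index("uptake_su"),
                        PROCESS_NAMES.index("uptake_h2") + 1)
        assert np.all(rho[uptakes] == 0.0)

    def test_monod_saturation_limit(self, params, manure, prairie):
        """Far above the half-saturation the uptake no longer depends on S."""
        model = self._model(manure, prairie, params)
        base = np.zeros(N_STATES)
        base[IDX["X_su"]] = 2.0
        base[IDX["S_IN"]] = 0.1
        base[IDX["S_cat"]] = 0.1
        base[IDX["S_IC"]] = 0.1
        j = PROCESS_NAMES.index("uptake_su")
        rates = []
        for mult in (1e3, 1e6):
            s = base.copy()
            s[IDX["S_su"]] = mult * params.K_S_su
            rates.append(model.process_rates(s)[0][j])
        assert rates[0] == pytest.approx(rates[1], rel=2e-3)

    def test_rates_nonnegative_on_random_states(self, params, manure, prairie):
        model = self._model(manure, prairie, params)
        for state in _random_states(200, seed=3):
            rho, _ = model.process_rates(state)
            assert np.all(rho >= 0.0)

    def test_zero_influent_zero_state_stationary(self, params):
        inf = fs.InfluentSpec(X_c=0.0, flow=100.0)
        model = ADM1Model(inf, params, influent_S_IC=0.0,
                          influent_S_cat=0.0, influent_S_an=0.0)
        dy = model.rhs(0.0, np.zeros(N_STATES))
        assert np.max(np.abs(dy)) < 1e-12


class TestSimulation:
    def test_steady_state_flag_and_ph(self, manure_simulation):
        res = manure_simulation
        assert res.is_steady
        assert 6.5 < res.pH < 8.0
        assert res.gas_flow > 0

    def test_intensive_in_flow(self, params, manure, prairie):
        """Scaling the influent flow (reactor sized along) leaves the steady
        state unchanged: the model is intensive."""
        inf = fs.blend_influent(prairie, manure, 1.0)
        big = dataclasses.replace(inf, flow=2.0 * inf.flow)
        r1 = simulate_cstr(inf, params)
        r2 = simulate_cstr(big, params)
        np.testing.assert_allclose(r2.steady_state, r1.steady_state,
                                   rtol=1e-8, atol=1e-12)
        assert r2.gas_flow == pytest.approx(2.0 * r1.gas_flow, rel=1e-8)

    def test_steady_state_independent_of_initialization(
            self, params, manure, prairie, manure_simulation):
        """Two distinct feasible starts converge to the same operating point."""
        inf = fs.blend_influent(prairie, manure, 0.0)
        y_star = manure_simulation.steady_state
        rng = np.random.default_rng(42)
        results = []
        for _ in range(2):
            y0 = y_star * rng.uniform(0.7, 1.3, size=y_star.shape)
            res = simulate_cstr(inf, params, initial_state=y0)
            results.append(res.steady_state)
        scale = np.abs(y_star) + 1e-8
        rel = np.abs(results[0] - results[1]) / scale
        assert np.max(rel) < 1e-4

    def test_methanogen_knockout_kills_ch4(self, params, manure, prairie):
        """Crippling both methanogen groups drives the CH4 yield to ~0."""
        inf = fs.blend_influent(prairie, manure, 0.0)
        crippled = params.with_overrides({"k_m_ac": 0.01, "k_m_h2": 0.01})
        res = simulate_cstr(inf, crippled, duration=90.0,
                            raise_on_failure=False, polish=False)
        yl = yield_report(res, vs_rate=24000.0, force=True)
        healthy = 192.0  # manure mono-digestion at intact defaults
        assert yl.ch4_yield < 0.1 * healthy

    def test_negative_hrt_rejected(self, params, manure, prairie):
        inf = fs.blend_influent(prairie, manure, 0.0)
        with pytest.raises(ValueError):
            simulate_cstr(inf, params, HRT=-1.0)


class TestYieldReport:
    def _dummy_result(self, molar, steady=True):
        return SimulationResult(
            time=np.array([0.0]), states=np.zeros((1, N_STATES)),
            steady_state=np.zeros(N_STATES), is_steady=steady, pH=7.0,
            gas_flow=1.0, gas_pressures={}, molar_flows=molar,
            diagnostics={}, model=None)

    def test_zero_gas_guard(self):
        res = self._dummy_result({"H2": 0.0, "CH4": 0.0, "CO2": 0.0})
        with pytest.warns(UserWarning, match="zero gas"):
            yl = yield_report(res, vs_rate=100.0)
        assert yl.ch4_yield == 0.0

    def test_pure_methane_stream(self):
        res = self._dummy_result({"H2": 0.0, "CH4": 3.0, "CO2": 0.0})
        yl = yield_report(res, vs_rate=100.0)
        assert yl.ch4_fraction == 1.0
        assert yl.ch4_yield == yl.biogas_yield

    def test_non_steady_rejected_unless_forced(self):
        res = self._dummy_result({"H2": 0.0, "CH4": 1.0, "CO2": 1.0},
                                 steady=False)
        with pytest.raises(Exception, match="steady"):
            yield_report(res, vs_rate=100.0)
        assert yield_report(res, vs_rate=100.0, force=True).ch4_fraction == 0.5

    def test_ch4_never_exceeds_biogas(self, manure_simulation):
        yl = yield_report(manure_simulation, vs_rate=24000.0)
        assert 0.0 < yl.ch4_yield <= yl.biogas_yield
        assert 0.0 < yl.ch4_fraction < 1.0


class TestParameters:
    def test_unknown_override_rejected(self):
        with pytest.raises(KeyError, match="k_m_zz"):
            ADM1Parameters().with_overrides({"k_m_zz": 1.0})

    def test_ph_window_ordering_enforced(self):
        with pytest.raises(ValueError, match="pH_UL"):
            ADM1Parameters(pH_UL_ac=6.0, pH_LL_ac=7.0)

    def test_yaml_roundtrip(self, tmp_path):
        p = ADM1Parameters(k_dis=0.7)
        path = tmp_path / "params.yaml"
        p.to_yaml(path)
        q = ADM1Parameters.from_yaml(path)
        assert q.k_dis == 0.7
        assert q.k_m_ac == p.k_m_ac

    def test_temperature_correction_direction(self):
        cold = ADM1Parameters(T_op=298.15)
        warm = ADM1Parameters(T_op=308.15)
        assert warm.K_a_IN > cold.K_a_IN        # ammonia more acidic when warm
        assert warm.K_H_ch4 < cold.K_H_ch4      # gases less soluble when warm
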