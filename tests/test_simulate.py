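"""Assembly, integration, observables, and conservation structure."""

import copy

import numpy as np
import pandas as pd
import pytest

import methanokin as mk
from methanokin.growth import ProteomeAllocation
from methanokin.network import CARBON_WEIGHTS, CONSERVED_POOLS
from methanokin.simulate import (
    ConfigurationError,
    KineticGrowthModel,
    Scenario,
    TimeCourse,
    efflux_ratio,
    methane_rate,
)


class TestAssembly:
    def test_zero_state_zero_derivative(self):
        model = KineticGrowthModel(scenario=Scenario())
        f = model.rhs()
        y = np.zeros(len(model.dynamic_species) + 1)
        assert np.all(f(0.0, y) == 0.0)

    def test_no_substrate_no_methane_derivative(self):
        model = KineticGrowthModel(scenario=Scenario(substrate_mM=0.0))
        y0 = model.initial_state()
        dy = model.rhs()(0.0, y0)
        assert dy[model._index["CH4"]] == 0.0

    def test_missing_enzyme_is_configuration_error(self, methanol_alloc):
        stoich = dict(methanol_alloc.stoichiometries)
        stoich.pop("Mcr")
        bad = ProteomeAllocation(stoichiometries=stoich)
        with pytest.raises(ConfigurationError, match="Mcr"):
            KineticGrowthModel(allocation=bad, scenario=Scenario())

    def test_carrier_pool_derivatives_cancel(self, random_states):
        """Moiety-pool sums are algebraically invariant at any state."""
        model, states = random_states
        f = model.rhs()
        idx = model._index
        for y in states:
            dy = f(0.0, y)
            gross = np.max(np.abs(dy)) + 1e-30
            for members in CONSERVED_POOLS.values():
                total = sum(dy[idx[m]] for m in members if m in idx)
                assert abs(total) <= 1e-10 * gross

    def test_carbon_conservation_at_random_states(self, random_states):
        model, states = random_states
        f = model.rhs()
        idx = model._index
        for y in states:
            dy = f(0.0, y)
            gross = np.max(np.abs(dy)) + 1e-30
            carbon = sum(w * dy[idx[sp]] for sp, w in CARBON_WEIGHTS.items()
                         if sp in idx)
            assert abs(carbon) <= 1e-10 * gross


class TestRun:
    def test_methanol_monotone_series(self, methanol_tc):
        meoh = methanol_tc.concentration("MeOH")
        assert np.all(np.diff(meoh) <= 1e-9)
        assert np.all(np.diff(methanol_tc.data["ch4_cum_umol"]) >= -1e-9)
        assert np.all(np.diff(methanol_tc.data["co2_cum_umol"]) >= -1e-9)

    def test_acetate_consumption_starts(self, acetate_tc):
        ac = acetate_tc.concentration("Ac")
        assert ac[-1] < ac[0]
        assert acetate_tc.data["ch4_cum_umol"].iloc[-1] > 0

    def test_nonnegative_within_solver_tolerance(self, methanol_tc):
        conc = methanol_tc.data[methanol_tc.species].to_numpy()
        assert conc.min() > -1e-6

    def test_cell_mass_bounded_by_atp_throughput(self, methanol_tc):
        # growth cannot exceed yield x (total ATP turned over); a generous
        # upper bound is the substrate electron budget plus initial pools
        gain = methanol_tc.cell_mass_mg[-1] - methanol_tc.cell_mass_mg[0]
        max_atp_umol = 125.0 * 13.0 / 4.0 + 11.0
        assert 0 < gain < 15.4e-3 * max_atp_umol

    def test_conservation_along_trajectory(self, methanol_tc):
        pools = methanol_tc.pool_totals()
        for name, series in pools.items():
            s = series.to_numpy()
            assert np.max(np.abs(s - s[0])) <= 1e-6 * max(s[0], 1e-12), name

    def test_carbon_conserved_along_trajectory(self, methanol_tc):
        df = methanol_tc.data
        carbon = sum(w * df[sp] for sp, w in CARBON_WEIGHTS.items()
                     if sp in df.columns)
        c = carbon.to_numpy()
        assert np.max(np.abs(c - c[0])) <= 1e-6 * c[0]

    def test_exhaustion_event_stops_run(self, methanol_exhaustion_tc):
        tc = methanol_exhaustion_tc
        assert tc.concentration("MeOH")[-1] == pytest.approx(1e-3, rel=0.05)
        assert tc.time_h[-1] < 30000.0

    def test_intensivity_under_volume_scaling(self, network):
        scen1 = Scenario(duration_h=20.0, sample_h=0.5)
        tc1 = KineticGrowthModel(scenario=scen1).simulate()
        net2 = copy.deepcopy(network)
        net2.volume = 2.0
        scen2 = scen1.replace(initial_cell_mass_mg=0.2)
        tc2 = KineticGrowthModel(net2, None, scen2).simulate()
        for sp in ("MeOH", "ATP", "CH4", "CoM"):
            assert np.allclose(tc1.concentration(sp), tc2.concentration(sp),
                               rtol=1e-6, atol=1e-9), sp
        assert np.allclose(2 * tc1.cell_mass_mg, tc2.cell_mass_mg, rtol=1e-6)


class TestRK4Oracle:
    def test_fixed_step_rk4_matches_adaptive(self):
        """Independent fixed-step integration agrees with the stiff solver."""
        scen = Scenario(duration_h=1.0, stop_at_exhaustion=False)
        model = KineticGrowthModel(scenario=scen)
        f = model.rhs()
        y = model.initial_state().copy()
        dt, T = 0.01, 3600.0
        n = int(round(T / dt))
        for _ in range(n):
            k1 = f(0.0, y)
            k2 = f(0.0, y + 0.5 * dt * k1)
            k3 = f(0.0, y + 0.5 * dt * k2)
            k4 = f(0.0, y + dt * k3)
            y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        tc = model.simulate(t_eval=np.array([0.0, 1.0]))
        y_ada = tc.data.iloc[-1][model.dynamic_species + ["cell_mass_mg"]]
        y_ada = y_ada.to_numpy(dtype=float)
        # species drained to sub-0.1 nM are compared absolutely at that
        # scale; everything else relatively
        rel = np.abs(y - y_ada) / np.maximum(np.abs(y_ada), 1e-4)
        assert rel.max() <= 1e-4


class TestObservables:
    @staticmethod
    def _linear_tc(c=2.5, n=50):
        t = np.linspace(0.0, 10.0, n)
        df = pd.DataFrame({"time_h": t, "cell_mass_mg": 0.1 + 0 * t,
                           "ch4_cum_umol": c * t, "co2_cum_umol": c * t / 3})
        return TimeCourse(df, Scenario(), [])

    def test_methane_rate_of_linear_series(self):
        tc = self._linear_tc(c=2.5)
        # c umol/h -> nmol/mL/min
        assert methane_rate(tc) == pytest.approx(2.5 * 1000 / 60)

    def test_methane_rate_needs_resolution(self):
        t = np.array([0.0, 1.0])
        df = pd.DataFrame({"time_h": t, "cell_mass_mg": [0.1, 0.1],
                           "ch4_cum_umol": [0.0, 1.0],
                           "co2_cum_umol": [0.0, 1.0]})
        with pytest.raises(ValueError, match="few samples"):
            methane_rate(TimeCourse(df, Scenario(), []))

    def test_efflux_ratio_linear(self):
        assert efflux_ratio(self._linear_tc()) == pytest.approx(3.0)

    def test_efflux_ratio_zero_co2(self):
        t = np.linspace(0, 1, 5)
        df = pd.DataFrame({"time_h": t, "cell_mass_mg": 0.1 + 0 * t,
                           "ch4_cum_umol": t, "co2_cum_umol": 0 * t})
        with pytest.raises(ZeroDivisionError):
            efflux_ratio(TimeCourse(df, Scenario(), []))

    def test_time_grid_must_increase(self):
        df = pd.DataFrame({"time_h": [0.0, 0.0, 1.0],
                           "cell_mass_mg": [0.1] * 3,
                           "ch4_cum_umol": [0.0] * 3,
                           "co2_cum_umol": [0.0] * 3})
        with pytest.raises(ValueError, match="increasing"):
            TimeCourse(df, Scenario(), [])


class TestStoichiometricOracle:
    def test_closed_network_forces_three_to_one(self, network):
        """Flux balance on the transcribed stoichiometry yields 4 MeOH ->
        3 CH4 + 1 CO2, independently of any kinetics."""
        from scipy.optimize import linprog

        rxns = [r for r in network.reactions if r.mechanism != "F"]
        balanced_roles = {"carrier", "intermediate"}
        balanced = [sp.name for sp in network.species
                    if network.species_role(sp.name) in balanced_roles]
        sp_index = {sp: i for i, sp in enumerate(balanced)}

        def net_stoich(rxn, sp):
            return rxn.product_stoich.get(sp, 0.0) - rxn.reactant_stoich.get(
                sp, 0.0)

        A_eq = np.zeros((len(balanced) + 2, len(rxns)))
        for j, rxn in enumerate(rxns):
            for sp, i in sp_index.items():
                A_eq[i, j] = net_stoich(rxn, sp)
            A_eq[-2, j] = net_stoich(rxn, "Ac")
            A_eq[-1, j] = net_stoich(rxn, "MeOH")
        b_eq = np.zeros(len(balanced) + 2)
        b_eq[-2] = 0.0  # methanol-only growth: no net acetate exchange
        b_eq[-1] = -4.0  # consume exactly 4 methanol

        c = -np.array([net_stoich(r, "CH4") for r in rxns])
        res = linprog(c, A_eq=A_eq, b_eq=b_eq,
                      bounds=[(0, 1e4)] * len(rxns), method="highs")
        assert res.status == 0
        ch4 = -res.fun
        co2 = sum(net_stoich(r, "CO2") * v for r, v in zip(rxns, res.x))
        assert ch4 == pytest.approx(3.0, abs=1e-8)
        assert co2 == pytest.approx(1.0, abs=1e-8)

    def test_simulated_ratio_at_exhaustion(self, methanol_exhaustion_tc):
        assert methanol_exhaustion_tc.efflux_ratio() == pytest.approx(
            3.0, rel=1e-3
        )
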