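"""Dynamic FBA stepping: kinetics, update rules, conservation, stability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import CELL_MASS, LTEE_GLUCOSE, fresh_environment
from evofba import (
    Environment,
    Genotype,
    PopulationState,
    dfba_step,
    run_cycle,
    uptake_capacity,
)

LN2_60 = math.log(2.0) * 60.0


class TestUptakeCapacity:
    def test_printed_example(self):
        """v_max 10 at 0.1389 mmol/l with K_m 0.01: 10*0.1389/0.1489."""
        assert uptake_capacity(10.0, 0.1389, 0.01) == pytest.approx(9.3284, abs=1e-4)

    def test_zero_substrate_zero_uptake(self):
        assert uptake_capacity(12.3, 0.0, 0.01) == 0.0

    def test_saturation(self):
        assert uptake_capacity(10.0, 1e9, 0.01) == pytest.approx(10.0, rel=1e-6)

    @given(
        v=st.floats(0.0, 40.0),
        s=st.floats(0.0, 10.0),
        km=st.floats(1e-6, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_bounded_and_monotone(self, v, s, km):
        cap = uptake_capacity(v, s, km)
        assert 0.0 <= cap <= v
        assert uptake_capacity(v, s + 0.1, km) >= cap - 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            uptake_capacity(-1.0, 0.1, 0.01)
        with pytest.raises(ValueError):
            uptake_capacity(1.0, -0.1, 0.01)
        with pytest.raises(ValueError):
            uptake_capacity(1.0, 0.1, 0.0)


class TestUpdateRules:
    def test_biomass_update_linearised_form(self, toy_model, toy_solver, toy_ancestor):
        """mu = ln 2 per hour grows biomass by the factor 1 + 1/60 per minute."""
        from evofba.dynamics import _growth_factor

        assert 0.001 * _growth_factor(math.log(2.0), 1.0, "paper") == pytest.approx(
            1.0166667e-3, rel=1e-6
        )

    def test_concentration_update_arithmetic(self, toy_model, toy_solver):
        """0.1389 - 0.006*9.3284/(60*0.01) = 0.0456 mmol/l after one minute.

        Engineered on the toy model: biomass and caps chosen so realised
        glucose uptake is exactly the Michaelis-Menten capacity."""
        g = Genotype(1, None, {"EX_glc": 10.0, "EX_ac": 0.0, "EX_o2": 30.0})
        env = Environment({"EX_glc": 0.1389, "EX_ac": 0.0}, 0.01, frozenset({"EX_o2"}))
        pops = PopulationState({1: 0.006}, CELL_MASS)
        env2, pops2, sols = dfba_step(env, pops, {1: g}, toy_solver)
        v_glc = sols[1].exchange_fluxes["EX_glc"]
        assert v_glc == pytest.approx(9.3284, abs=1e-4)
        expected = 0.1389 - 0.006 * v_glc / (60.0 * 0.01)
        assert env2.concentrations["EX_glc"] == pytest.approx(expected, rel=1e-12)
        assert env2.concentrations["EX_glc"] == pytest.approx(0.0456, abs=1e-4)

    def test_secretion_raises_concentration(self, core_model, core_solver, ancestor):
        env = fresh_environment(core_model, volume=0.01)
        pops = PopulationState({1: 1e-4}, CELL_MASS)
        env2, _, sols = dfba_step(env, pops, {1: ancestor}, core_solver)
        assert sols[1].exchange_fluxes["EX_ac_e"] < 0  # overflow secretion
        assert env2.concentrations["EX_ac_e"] > 0.0

    def test_empty_population_leaves_environment_unchanged(self, toy_solver):
        env = Environment({"EX_glc": 0.1, "EX_ac": 0.0}, 0.01, frozenset({"EX_o2"}))
        pops = PopulationState({}, CELL_MASS)
        env2, pops2, sols = dfba_step(env, pops, {}, toy_solver)
        assert env2.concentrations == env.concentrations
        assert sols == {}

    def test_exponential_update_option(self):
        from evofba.dynamics import _growth_factor

        assert _growth_factor(0.6, 1.0, "exponential") == pytest.approx(
            math.exp(0.01), rel=1e-12
        )


class TestConservationAndStability:
    def test_concentrations_never_negative(self, toy_model, toy_solver, toy_ancestor):
        """Overshoot handling clamps depleted substrates at exactly zero."""
        env = fresh_environment(toy_model, volume=1e-6)
        pops = PopulationState({1: 50_000 * CELL_MASS}, CELL_MASS)
        traj, env_end, _ = run_cycle(
            env, pops, {1: toy_ancestor}, toy_solver, hours=6.0, dt=5.0
        )
        for conc in traj.concentrations:
            for s, c in conc.items():
                assert c >= 0.0

    def test_carbon_accounting_on_toy(self, toy_model, toy_solver, toy_ancestor):
        """No carbon creation: per step, carbon uptake >= carbon fixed in
        biomass plus carbon secreted (the toy fixture defines contents:
        glc 6, ac 2, prec 2, biomass 200 per unit growth flux)."""
        env = fresh_environment(toy_model, volume=1e-6)
        pops = PopulationState({1: 10_000 * CELL_MASS}, CELL_MASS)
        genotypes = {1: toy_ancestor}
        for _ in range(200):
            env, pops, sols = dfba_step(env, pops, genotypes, toy_solver, dt=5.0)
            for sol in sols.values():
                vg = sol.exchange_fluxes["EX_glc"]
                va = sol.exchange_fluxes["EX_ac"]
                vp = sol.exchange_fluxes["EX_prec"]
                carbon_in = 6.0 * max(vg, 0.0) + 2.0 * max(va, 0.0)
                carbon_out = (
                    200.0 * sol.growth_rate
                    + 2.0 * max(-va, 0.0)
                    + 2.0 * max(-vp, 0.0)
                )
                # LP primal tolerance is relative to flux magnitude
                assert carbon_in >= carbon_out - 1e-6 * max(1.0, carbon_out)

    def test_biomass_nondecreasing_within_cycle(self, ancestor_day):
        traj, _, _ = ancestor_day
        bm = np.array([b[1] for b in traj.biomass])
        assert (np.diff(bm) >= -1e-18).all()

    def test_glucose_monotonically_nonincreasing(self, ancestor_day):
        traj, _, _ = ancestor_day
        glc = np.array([c["EX_glc__D_e"] for c in traj.concentrations])
        assert (np.diff(glc) <= 1e-15).all()

    def test_zero_substrate_flat_biomass(self, toy_model, toy_solver, toy_ancestor):
        env = fresh_environment(toy_model, volume=1e-6, glucose=0.0)
        pops = PopulationState({1: 1_000 * CELL_MASS}, CELL_MASS)
        traj, _, pops_end = run_cycle(
            env, pops, {1: toy_ancestor}, toy_solver, hours=24.0, dt=30.0
        )
        assert pops_end.biomass[1] == pytest.approx(1_000 * CELL_MASS, rel=1e-12)

    def test_determinism(self, toy_model, toy_solver, toy_ancestor):
        """Identical inputs give bit-identical trajectories."""
        def run():
            env = fresh_environment(toy_model, volume=1e-6)
            pops = PopulationState({1: 1_000 * CELL_MASS}, CELL_MASS)
            traj, _, pops_end = run_cycle(
                env, pops, {1: toy_ancestor}, toy_solver, hours=1.0, dt=1.0
            )
            return traj, pops_end

        t1, p1 = run()
        t2, p2 = run()
        assert p1.biomass == p2.biomass
        assert t1.concentrations == t2.concentrations

    def test_halving_dt_changes_final_biomass_below_one_percent(
        self, core_model, core_solver, ancestor
    ):
        """Euler stability on the ancestor scenario."""
        finals = []
        for dt in (2.0, 1.0):
            env = fresh_environment(core_model, volume=0.01)
            pops = PopulationState({1: 1_000_000 * CELL_MASS}, CELL_MASS)
            _, _, pops_end = run_cycle(
                env, pops, {1: ancestor}, core_solver, hours=24.0, dt=dt
            )
            finals.append(pops_end.biomass[1])
        assert abs(finals[1] - finals[0]) / finals[1] < 0.01

    def test_final_biomass_regression(self, ancestor_day):
        """Golden value for the ancestor's 24-h growth from 1e6 cells in
        0.1389 mmol/l glucose (pinned on the first correct build)."""
        _, _, pops_end = ancestor_day
        assert pops_end.biomass[1] == pytest.approx(ANCESTOR_DAY_FINAL_GDW, rel=1e-6)


# pinned on the first correct build of the dynamics (golden regression)
ANCESTOR_DAY_FINAL_GDW = 0.00017187424439621927
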