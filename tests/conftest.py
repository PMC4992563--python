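import numpy as np
import pytest

import evofba
from evofba import (
    BudgetedFBASolver,
    Environment,
    Genotype,
    PopulationState,
    run_cycle,
)

ANCESTOR_VMAX = {"EX_glc__D_e": 10.0, "EX_ac_e": 10.0, "EX_o2_e": 20.0}
TOY_VMAX = {"EX_glc": 10.0, "EX_ac": 10.0, "EX_o2": 20.0}
LTEE_GLUCOSE = 0.1389  # mmol/l
CELL_MASS = 6e-13  # gDW


@pytest.fixture(scope="session")
def toy_model():
    return evofba.make_toy_model()


@pytest.fixture(scope="session")
def toy_solver(toy_model):
    return BudgetedFBASolver(toy_model, toy_model.mutable_exchanges(), 40.0)


@pytest.fixture(scope="session")
def core_model():
    return evofba.load_ancestor_model()


@pytest.fixture(scope="session")
def core_solver(core_model):
    return BudgetedFBASolver(core_model, core_model.mutable_exchanges(), 40.0)


def full_vmax(model, entries):
    v = {ex: 0.0 for ex in model.mutable_exchanges()}
    v.update(entries)
    return v


@pytest.fixture(scope="session")
def ancestor(core_model):
    return Genotype(1, None, full_vmax(core_model, ANCESTOR_VMAX))


@pytest.fixture(scope="session")
def toy_ancestor(toy_model):
    return Genotype(1, None, full_vmax(toy_model, TOY_VMAX))


def fresh_environment(model, volume, glucose=LTEE_GLUCOSE):
    resolve = evofba.fixtures.alias_resolver(model)
    glc, o2 = resolve("glucose"), resolve("oxygen")
    tracked = [ex for ex in model.mutable_exchanges() if ex != o2]
    return Environment(
        {ex: (glucose if ex == glc else 0.0) for ex in tracked},
        volume,
        non_depleting=frozenset({o2}),
    )


@pytest.fixture(scope="session")
def ancestor_day(core_model, core_solver, ancestor):
    """One 24-h ancestor cycle at 1-min steps in LTEE glucose, with fluxes."""
    env = fresh_environment(core_model, volume=0.01)
    pops = PopulationState({1: 1_000_000 * CELL_MASS}, CELL_MASS)
    traj, env_end, pops_end = run_cycle(
        env, pops, {1: ancestor}, core_solver, record_exchange_fluxes=True
    )
    return traj, env_end, pops_end
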