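"""Batch-culture dynamic FBA: Michaelis-Menten uptake caps, Euler stepping.

One serial-transfer day is simulated as a sequence of short Euler steps
(1 min by default).  At each step, every genotype's realisable uptake for
each tracked substrate is capped by a Michaelis-Menten function of the
current medium concentration; FBA (two-stage, budgeted) yields the growth
rate and realised exchange fluxes; biomass and medium concentrations are
then updated with the discrete-time rules

    BM(t+dt) = BM(t) * (1 + mu * dt / (ln 2 * 60))
    [S](t+dt) = [S](t) - sum_i BM_i(t) * v_{i,S} * dt / (60 * V)

where mu is in 1/h, dt in minutes, BM in absolute gDW, [S] in mmol/l and
V in litres.  The default growth update is the linearised rule above with
its ln 2 divisor (``growth_update="paper"``), under which mu acts as
doublings per hour; a conventional exponential update exp(mu*dt/60) is
available as ``growth_update="exponential"``.

Oxygen (and any other substrate in ``Environment.non_depleting``) is not
tracked in the medium: a shaken batch flask is effectively aerated, so its
uptake cap each step is simply the genotype's v_max.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Iterable, Mapping

import numpy as np
import pandas as pd

from .solver import BudgetedFBASolver, FBASolution

if TYPE_CHECKING:  # pragma: no cover
    from .evolution import Genotype

__all__ = [
    "Environment",
    "PopulationState",
    "CycleTrajectory",
    "uptake_capacity",
    "dfba_step",
    "run_cycle",
    "DEFAULT_CELL_MASS",
]

LN2_60 = math.log(2.0) * 60.0

log = logging.getLogger(__name__)

#: Dry mass of one exponentially growing cell, gDW (600 fg).
DEFAULT_CELL_MASS = 6e-13

#: Concentrations below this are treated as exactly exhausted (mmol/l).
CONC_EPS = 1e-15


def uptake_capacity(v_max: float, S: float, K_m: float) -> float:
    """Michaelis-Menten bound on uptake: ``v_max * S / (K_m + S)``.

    Used as the per-substrate uptake cap handed to FBA each step; returns
    0 when the substrate is exhausted and saturates to ``v_max`` for
    S >> K_m.
    """
    if v_max < 0 or S < 0 or K_m <= 0:
        raise ValueError(f"require v_max >= 0, S >= 0, K_m > 0; got {(v_max, S, K_m)}")
    if S == 0.0:
        return 0.0
    return v_max * S / (K_m + S)


@dataclass
class Environment:
    """The shared medium: tracked substrate concentrations in a fixed volume.

    ``concentrations`` is keyed by exchange-reaction id (mmol/l); only
    depletable substrates appear.  ``non_depleting`` lists exchanged
    substrates whose concentration is not tracked (oxygen).
    """

    concentrations: dict[str, float]
    volume: float
    non_depleting: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("reactor volume must be positive")
        bad = {s: c for s, c in self.concentrations.items() if c < 0}
        if bad:
            raise ValueError(f"negative concentrations: {bad}")

    def copy(self) -> "Environment":
        return Environment(dict(self.concentrations), self.volume, self.non_depleting)


@dataclass
class PopulationState:
    """Absolute biomass (gDW) per genotype; cell counts are derived."""

    biomass: dict[int, float]
    cell_mass: float = DEFAULT_CELL_MASS

    def cells(self, genotype_id: int) -> int:
        return int(self.biomass.get(genotype_id, 0.0) / self.cell_mass)

    def cell_counts(self) -> dict[int, int]:
        return {g: int(b / self.cell_mass) for g, b in self.biomass.items()}

    def total_biomass(self) -> float:
        return sum(self.biomass.values())

    def alive(self) -> list[int]:
        return [g for g, b in self.biomass.items() if b > 0.0]

    def copy(self) -> "PopulationState":
        return PopulationState(dict(self.biomass), self.cell_mass)


@dataclass
class CycleTrajectory:
    """Record of one 24-h cycle: medium, biomass and (optionally) fluxes."""

    times: list[float] = field(default_factory=list)  # minutes
    concentrations: list[dict[str, float]] = field(default_factory=list)
    biomass: list[dict[int, float]] = field(default_factory=list)
    growth_rates: list[dict[int, float]] = field(default_factory=list)
    exchange_fluxes: list[dict[int, dict[str, float]]] | None = None
    full_fluxes: list[dict[int, np.ndarray]] | None = None

    def medium_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations)
        df.insert(0, "time_min", self.times)
        return df

    def biomass_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.biomass).fillna(0.0)
        df.columns = [f"genotype_{g}" for g in df.columns]
        df.insert(0, "time_min", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.medium_frame().merge(self.biomass_frame(), on="time_min").to_csv(
            path, sep="\t", index=False
        )

    def flux_table(self) -> pd.DataFrame:
        """Long-format per-step exchange fluxes: time_min, genotype_id,
        reaction_id, flux (uptake-positive)."""
        if self.exchange_fluxes is None:
            raise ValueError("trajectory was recorded without exchange fluxes")
        rows = []
        for t, step in zip(self.times, self.exchange_fluxes):
            for g, fluxes in step.items():
                for rxn, v in fluxes.items():
                    rows.append((t, g, rxn, v))
        return pd.DataFrame(rows, columns=["time_min", "genotype_id", "reaction_id", "flux"])

    def genotype_exchange_series(self, genotype_id: int, exchange_id: str) -> np.ndarray:
        """Uptake-positive flux of one exchange for one genotype over time."""
        if self.exchange_fluxes is None:
            raise ValueError("trajectory was recorded without exchange fluxes")
        return np.array(
            [step.get(genotype_id, {}).get(exchange_id, 0.0) for step in self.exchange_fluxes]
        )


def _growth_factor(mu: float, dt: float, growth_update: str) -> float:
    if growth_update == "paper":
        return 1.0 + mu * dt / LN2_60
    if growth_update == "exponential":
        return math.exp(mu * dt / 60.0)
    raise ValueError(f"unknown growth_update {growth_update!r}")


def _caps_for(
    genotype: "Genotype",
    env: Environment,
    km: float,
) -> dict[str, float]:
    caps = {}
    for ex, vmax in genotype.v_max.items():
        if ex in env.non_depleting:
            caps[ex] = vmax
        else:
            caps[ex] = uptake_capacity(vmax, env.concentrations.get(ex, 0.0), km)
    return caps


def dfba_step(
    env: Environment,
    pops: PopulationState,
    genotypes: Mapping[int, "Genotype"],
    solver: BudgetedFBASolver,
    *,
    km: float = 0.01,
    dt: float = 1.0,
    growth_update: str = "paper",
    record_full_fluxes: bool = False,
) -> tuple[Environment, PopulationState, dict[int, FBASolution]]:
    """Advance medium and population by one Euler step of length ``dt`` min.

    Mutates nothing: returns updated copies of the environment and
    population plus the per-genotype FBA solutions used for the step.

    If the step would drive a substrate concentration below zero, the
    uptake caps of that substrate are scaled by available/demand for all
    consuming genotypes, the affected genotypes are re-solved once, and
    the concentration is clamped at exactly 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new_env = env.copy()
    new_pops = pops.copy()
    solutions: dict[int, FBASolution] = {}

    live = [g for g in pops.biomass if pops.biomass[g] > 0.0]
    carbon_left = any(c > CONC_EPS for c in env.concentrations.values())

    caps_by_g: dict[int, dict[str, float]] = {}
    for g in live:
        caps = _caps_for(genotypes[g], env, km)
        caps_by_g[g] = caps
        if not carbon_left:
            # no tracked substrate in the medium: nothing to grow on
            solutions[g] = solver.zero_solution(record_full_fluxes)
        else:
            solutions[g] = solver.solve(caps, full_fluxes=record_full_fluxes)

    def deltas() -> dict[str, float]:
        d = {s: 0.0 for s in env.concentrations}
        for g in live:
            bm = pops.biomass[g]
            for s in d:
                v = solutions[g].exchange_fluxes.get(s, 0.0)  # uptake-positive
                d[s] -= bm * v * dt / (60.0 * env.volume)
        return d

    delta = deltas()
    overshoot = [s for s, d in delta.items() if env.concentrations[s] + d < 0.0]
    if overshoot:
        rescale: dict[int, dict[str, float]] = {}
        for s in overshoot:
            demand = sum(
                pops.biomass[g] * max(solutions[g].exchange_fluxes.get(s, 0.0), 0.0)
                for g in live
            ) * dt / (60.0 * env.volume)
            supply = env.concentrations[s] + sum(
                pops.biomass[g] * max(-solutions[g].exchange_fluxes.get(s, 0.0), 0.0)
                for g in live
            ) * dt / (60.0 * env.volume)
            factor = 0.0 if demand <= 0 else min(supply / demand, 1.0)
            for g in live:
                if solutions[g].exchange_fluxes.get(s, 0.0) > 0.0:
                    rescale.setdefault(g, {})[s] = factor
        for g, factors in rescale.items():
            caps = dict(caps_by_g[g])
            for s, f in factors.items():
                caps[s] *= f
            solutions[g] = solver.solve(caps, full_fluxes=record_full_fluxes)
        delta = deltas()

    for s in new_env.concentrations:
        new_env.concentrations[s] = max(env.concentrations[s] + delta[s], 0.0)

    for g in live:
        mu = solutions[g].growth_rate
        new_pops.biomass[g] = pops.biomass[g] * _growth_factor(mu, dt, growth_update)

    return new_env, new_pops, solutions


def run_cycle(
    env: Environment,
    pops: PopulationState,
    genotypes: dict[int, "Genotype"],
    solver: BudgetedFBASolver,
    *,
    hours: float = 24.0,
    dt: float = 1.0,
    km: float = 0.01,
    growth_update: str = "paper",
    record_exchange_fluxes: bool = False,
    record_full_fluxes: bool = False,
    on_step: Callable[..., None] | None = None,
) -> tuple[CycleTrajectory, Environment, PopulationState]:
    """Run one batch-growth cycle of ``hours`` h in steps of ``dt`` min.

    ``on_step(step_index, env, pops, solutions)`` is called after each
    Euler update; the evolution engine hooks in here to draw mutations
    (it may add genotypes to ``genotypes`` and biomass to ``pops``).
    """
    n_steps = int(round(hours * 60.0 / dt))
    traj = CycleTrajectory(
        exchange_fluxes=[] if record_exchange_fluxes or record_full_fluxes else None,
        full_fluxes=[] if record_full_fluxes else None,
    )
    traj.times.append(0.0)
    traj.concentrations.append(dict(env.concentrations))
    traj.biomass.append(dict(pops.biomass))
    traj.growth_rates.append({g: 0.0 for g in pops.biomass})
    if traj.exchange_fluxes is not None:
        traj.exchange_fluxes.append({})
    if traj.full_fluxes is not None:
        traj.full_fluxes.append({})

    for step in range(1, n_steps + 1):
        env, pops, sols = dfba_step(
            env,
            pops,
            genotypes,
            solver,
            km=km,
            dt=dt,
            growth_update=growth_update,
            record_full_fluxes=record_full_fluxes,
        )
        if on_step is not None:
            on_step(step, env, pops, sols)
        if log.isEnabledFor(logging.DEBUG):
            log.debug(
                "step %d (t=%.0f min): %d genotypes, total biomass %.4g gDW, %s",
                step, step * dt, len(sols), pops.total_biomass(),
                {s: round(c, 6) for s, c in env.concentrations.items() if c > 0},
            )
        traj.times.append(step * dt)
        traj.concentrations.append(dict(env.concentrations))
        traj.biomass.append(dict(pops.biomass))
        traj.growth_rates.append({g: s.growth_rate for g, s in sols.items()})
        if traj.exchange_fluxes is not None:
            traj.exchange_fluxes.append({g: dict(s.exchange_fluxes) for g, s in sols.items()})
        if traj.full_fluxes is not None:
            traj.full_fluxes.append(
                {g: s.fluxes for g, s in sols.items() if s.fluxes is not None}
            )
    return traj, env, pops
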