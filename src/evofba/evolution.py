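"""Mutation of uptake capacities under a fixed total-uptake budget.

The evolvable unit (:class:`Genotype`) is a vector of maximum uptake rates
(v_max, mmol/gDW/h) over the mutable exchange reactions — for the E. coli
core chassis, 14 carbon sources plus oxygen.  A mutation picks one of
these at random, perturbs it by a step drawn uniformly from (-A, A),
clamps the result into [0, C_total], and rescales all other entries
proportionally so the vector always sums to the budget C_total
(40 mmol/gDW/h).  Mutations therefore redistribute a fixed transport /
respiration capacity rather than create new capacity — the tradeoff that
drives specialisation.

Mutational supply per time step follows the expected number of newly
mutated cells, N_m = N * mu * dt / (ln 2 * 60) * rate, with at most one
mutant introduced per genotype per step: N_m < 1 is used as a Bernoulli
probability and N_m >= 1 always yields exactly one mutant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dynamics import PopulationState

__all__ = [
    "Genotype",
    "MutationEvent",
    "GenotypeRegistry",
    "expected_mutants",
    "draw_mutation_count",
    "mutate",
    "spawn_mutant",
]

LN2_60 = math.log(2.0) * 60.0
BUDGET_TOL = 1e-9


@dataclass(frozen=True)
class Genotype:
    """One heritable uptake strategy.

    ``genotype_id`` 1 is the ancestor; children get sequential ids in
    order of creation.  ``birth`` is the (cycle, step) of the mutation
    that created the genotype.
    """

    genotype_id: int
    parent_id: int | None
    v_max: dict[str, float]
    birth: tuple[int, int] = (0, 0)

    def total_uptake(self) -> float:
        return sum(self.v_max.values())

    def validate(self, c_total: float) -> None:
        if abs(self.total_uptake() - c_total) > BUDGET_TOL:
            raise ValueError(
                f"genotype {self.genotype_id}: v_max sums to {self.total_uptake()}, "
                f"expected {c_total}"
            )
        bad = {ex: v for ex, v in self.v_max.items() if v < 0 or v > c_total}
        if bad:
            raise ValueError(f"v_max entries outside [0, {c_total}]: {bad}")


@dataclass(frozen=True)
class MutationEvent:
    parent_id: int
    child_id: int
    mutated_exchange: str
    step_size: float  # the raw draw a ~ U(-A, A)
    birth: tuple[int, int]


def expected_mutants(N: float, mu: float, rate: float = 1e-6, dt: float = 1.0) -> float:
    """Expected number of newly mutated cells in one step.

    ``N * mu * dt / (ln 2 * 60) * rate``: the per-minute number of cell
    divisions (growth rate mu in 1/h over N cells) times the per-cell,
    per-generation mutation rate, over a step of ``dt`` minutes.
    """
    if N < 0 or mu < 0 or rate <= 0 or dt <= 0:
        raise ValueError(f"require N, mu >= 0 and rate, dt > 0; got {(N, mu, rate, dt)}")
    return N * mu * dt / LN2_60 * rate


def draw_mutation_count(N_m: float, rng: np.random.Generator) -> int:
    """0 or 1 mutants this step: Bernoulli(N_m) below 1, always 1 at >= 1."""
    if N_m < 0:
        raise ValueError("expected mutant count must be >= 0")
    if N_m >= 1.0:
        return 1
    if N_m == 0.0:
        return 0
    return int(rng.random() < N_m)


def mutate(
    parent: Genotype,
    rng: np.random.Generator,
    step_bound: float = 10.0,
    *,
    c_total: float = 40.0,
    child_id: int,
    birth: tuple[int, int] = (0, 0),
) -> tuple[Genotype, MutationEvent]:
    """Create a mutant child genotype from ``parent``.

    One mutable exchange m is chosen uniformly; its v_max is shifted by
    a ~ Uniform(-step_bound, step_bound) and clamped into [0, c_total]
    *before* the remaining entries are rescaled to the leftover budget —
    the only order under which the leftover (c_total - v_max_m) is
    guaranteed non-negative.  When all other entries are zero, the
    leftover budget is spread uniformly over them.
    """
    exchanges = list(parent.v_max)
    m = exchanges[int(rng.integers(len(exchanges)))]
    a = float(rng.uniform(-step_bound, step_bound))

    v_m_new = min(max(parent.v_max[m] + a, 0.0), c_total)
    others = [ex for ex in exchanges if ex != m]
    other_sum = sum(parent.v_max[ex] for ex in others)
    leftover = c_total - v_m_new

    child_v = {m: v_m_new}
    if other_sum > 0.0:
        for ex in others:
            child_v[ex] = parent.v_max[ex] / other_sum * leftover
    else:
        for ex in others:
            child_v[ex] = leftover / len(others)

    child = Genotype(
        genotype_id=child_id,
        parent_id=parent.genotype_id,
        v_max={ex: child_v[ex] for ex in exchanges},  # preserve ordering
        birth=birth,
    )
    child.validate(c_total)
    event = MutationEvent(
        parent_id=parent.genotype_id,
        child_id=child_id,
        mutated_exchange=m,
        step_size=a,
        birth=birth,
    )
    return child, event


def spawn_mutant(
    pops: PopulationState,
    parent_id: int,
    child: Genotype,
) -> PopulationState:
    """Move exactly one cell of biomass from parent to the new mutant.

    Total biomass is conserved.  A parent below one cell cannot found a
    mutant; the population is returned unchanged.
    """
    if pops.cells(parent_id) < 1:
        return pops
    new = pops.copy()
    new.biomass[parent_id] -= new.cell_mass
    new.biomass[child.genotype_id] = new.cell_mass
    return new


class GenotypeRegistry:
    """All genotypes ever created, with their lineage and mutation events."""

    def __init__(self, ancestor: Genotype) -> None:
        if ancestor.genotype_id != 1:
            raise ValueError("the ancestor must have genotype_id 1")
        self.genotypes: dict[int, Genotype] = {1: ancestor}
        self.events: list[MutationEvent] = []
        self._next_id = 2

    def __len__(self) -> int:
        return len(self.genotypes)

    def __getitem__(self, genotype_id: int) -> Genotype:
        return self.genotypes[genotype_id]

    def __contains__(self, genotype_id: int) -> bool:
        return genotype_id in self.genotypes

    def new_mutant(
        self,
        parent_id: int,
        rng: np.random.Generator,
        step_bound: float,
        c_total: float,
        birth: tuple[int, int],
    ) -> tuple[Genotype, MutationEvent]:
        child, event = mutate(
            self.genotypes[parent_id],
            rng,
            step_bound,
            c_total=c_total,
            child_id=self._next_id,
            birth=birth,
        )
        self.genotypes[child.genotype_id] = child
        self.events.append(event)
        self._next_id += 1
        return child, event

    def write_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for g in self.genotypes.values():
                fh.write(
                    json.dumps(
                        {
                            "genotype_id": g.genotype_id,
                            "parent_id": g.parent_id,
                            "birth_cycle": g.birth[0],
                            "birth_step": g.birth[1],
                            "v_max": g.v_max,
                        }
                    )
                    + "\n"
                )


class EvolutionEngine:
    """Per-step mutation hook wired into :func:`evofba.dynamics.run_cycle`."""

    def __init__(
        self,
        registry: GenotypeRegistry,
        genotypes: dict[int, Genotype],
        rng: np.random.Generator,
        *,
        mutation_rate: float = 1e-6,
        step_bound: float = 10.0,
        c_total: float = 40.0,
        dt: float = 1.0,
    ) -> None:
        self.registry = registry
        self.genotypes = genotypes
        self.rng = rng
        self.mutation_rate = mutation_rate
        self.step_bound = step_bound
        self.c_total = c_total
        self.dt = dt
        self.cycle = 0

    def __call__(self, step: int, env, pops: PopulationState, solutions) -> None:
        if self.mutation_rate <= 0:
            return
        for g in list(pops.biomass):
            bm = pops.biomass[g]
            if bm <= 0.0:
                continue
            sol = solutions.get(g)
            mu = sol.growth_rate if sol is not None else 0.0
            if mu <= 0.0:
                continue
            n_cells = int(bm / pops.cell_mass)
            n_m = expected_mutants(n_cells, mu, self.mutation_rate, self.dt)
            if draw_mutation_count(n_m, self.rng) and pops.cells(g) >= 1:
                child, _ = self.registry.new_mutant(
                    g, self.rng, self.step_bound, self.c_total, (self.cycle, step)
                )
                self.genotypes[child.genotype_id] = child
                pops.biomass[g] -= pops.cell_mass
                pops.biomass[child.genotype_id] = pops.cell_mass
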