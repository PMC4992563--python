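"""Post-processing: survivors, lineage graphs, diauxie, flux snapshots.

These operations turn an :class:`~evofba.experiment.ExperimentResult` into
the summaries an experimenter looks at: which genotypes persisted through
transfers, how the surviving lineages relate to each other, when a
genotype switches from glucose to acetate within a day, and the full flux
map of a genotype in its glucose and acetate growth phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import CycleTrajectory, Environment, PopulationState, run_cycle
from .evolution import Genotype
from .experiment import ExperimentResult, dilute
from .model import StoichiometricModel
from .solver import BudgetedFBASolver

__all__ = [
    "survivors",
    "build_lineage_graph",
    "detect_diauxic_shift",
    "FluxSnapshot",
    "flux_snapshot_protocol",
    "cycles_to_generations",
    "REACTIONS_OF_INTEREST",
    "NoGrowthError",
]

#: Model reaction labels of the four enzymes tracked across lineages:
#: glucose-phosphate isomerase, aconitase, malate synthase (glyoxylate
#: shunt) and acetate kinase.
REACTIONS_OF_INTEREST = ("PGI", "ACONTb", "MALS", "ACKr")


def survivors(result: ExperimentResult, min_cycles: int = 1) -> list[int]:
    """Genotypes whose post-dilution count was >= 1 cell after at least
    ``min_cycles`` transfer events."""
    tally: dict[int, int] = {}
    for counts in result.post_dilution_cells:
        for g, n in counts.items():
            if n >= 1:
                tally[g] = tally.get(g, 0) + 1
    return sorted(g for g, c in tally.items() if c >= min_cycles)


def build_lineage_graph(
    result: ExperimentResult,
    min_peak_cells: float = 1e5,
    annotate: tuple[str, ...] | None = None,
) -> nx.DiGraph:
    """Ancestry forest over genotypes that ever reached ``min_peak_cells``.

    Nodes are the thresholded genotypes (the ancestor is always kept as
    root); each retained node is connected to its nearest retained
    ancestor, so edges contract through unretained intermediates.  Node
    annotations: ``peak_cells`` and, for each exchange in ``annotate``
    (default glucose/acetate/oxygen when present), the v_max relative to
    the budget.  Edge weight is log10 of the child's peak start-of-cycle
    (post-dilution) population.
    """
    registry = result.registry
    for g in registry.genotypes.values():
        if g.parent_id is not None and g.parent_id not in registry:
            raise ValueError(f"orphan genotype {g.genotype_id}: parent {g.parent_id} missing")

    retained = {g for g in registry.genotypes if result.peak_cells(g) >= min_peak_cells}
    retained.add(1)

    if annotate is None:
        sample = registry[1].v_max
        annotate = tuple(
            ex for ex in ("EX_glc__D_e", "EX_ac_e", "EX_o2_e", "EX_glc", "EX_ac", "EX_o2")
            if ex in sample
        )
    c_total = sum(registry[1].v_max.values())

    graph = nx.DiGraph(min_peak_cells=min_peak_cells)
    for g in sorted(retained):
        geno = registry[g]
        attrs = {"peak_cells": result.peak_cells(g)}
        for ex in annotate:
            attrs[f"rel_vmax_{ex}"] = geno.v_max.get(ex, 0.0) / c_total
        graph.add_node(g, **attrs)
    for g in sorted(retained - {1}):
        parent = registry[g].parent_id
        while parent is not None and parent not in retained:
            parent = registry[parent].parent_id
        if parent is None:
            parent = 1
        start_peak = max(
            (counts.get(g, 0) for counts in result.post_dilution_cells), default=0
        )
        graph.add_edge(parent, g, weight=math.log10(max(start_peak, 1)))
    return graph


def write_lineage_dot(graph: nx.DiGraph, path: str | Path) -> None:
    """Minimal deterministic DOT export (nodes ordered by genotype id)."""
    lines = ["digraph lineage {"]
    for node in sorted(graph.nodes):
        attrs = graph.nodes[node]
        label = f"{node}\\n{attrs.get('peak_cells', 0):.3g} cells"
        lines.append(f'  {node} [label="{label}"];')
    for u, v in sorted(graph.edges):
        w = graph.edges[u, v].get("weight", 1.0)
        lines.append(f"  {u} -> {v} [penwidth={max(w, 0.2):.2f}];")
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def detect_diauxic_shift(
    traj: CycleTrajectory,
    genotype_id: int,
    *,
    glucose_exchange: str = "EX_glc__D_e",
    acetate_exchange: str = "EX_ac_e",
    flux_tol: float = 1e-6,
    glucose_fraction: float | None = None,
) -> float | None:
    """First minute at which a genotype switches to net acetate consumption.

    The shift is the first time point where the acetate exchange turns
    from secretion to uptake, after a preceding phase of measurable
    acetate secretion (the overflow phase of growth on glucose).  Under
    growth-maximising FBA this switch marks the metabolic transition of
    the diauxie: it begins as soon as glucose no longer saturates the
    oxygen capacity, so a brief glucose/acetate co-utilisation window at
    the switch is part of the model's behaviour.  Pass ``glucose_fraction``
    (e.g. 0.01) to additionally require that glucose uptake has fallen
    below that fraction of its cycle maximum — the stricter, strictly
    sequential reading of the shift.

    Returns None when no switch occurs: a genotype that never secretes
    acetate, or never consumes it (e.g. an evolved glucose specialist
    with zero acetate uptake capacity).
    """
    glc = traj.genotype_exchange_series(genotype_id, glucose_exchange)
    ac = traj.genotype_exchange_series(genotype_id, acetate_exchange)
    glc_max = float(np.max(glc, initial=0.0))
    if glc_max <= 0.0:
        glc_max = flux_tol
    secreted = False
    for t, g_up, a_up in zip(traj.times, glc, ac):
        if a_up < -flux_tol:
            secreted = True
        if (
            secreted
            and a_up > flux_tol
            and (glucose_fraction is None or g_up < glucose_fraction * glc_max)
        ):
            return float(t)
    return None


class NoGrowthError(RuntimeError):
    """The genotype cannot grow under the snapshot protocol."""


@dataclass
class FluxSnapshot:
    """Full flux map of one genotype at one minute of the final cycle."""

    genotype_id: int
    phase: str  # "glucose" | "acetate"
    minute: float
    growth_rate: float
    fluxes: dict[str, float]
    reactions_of_interest: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r, v, r in self.reactions_of_interest)
            for r, v in self.fluxes.items()
        ]
        return pd.DataFrame(rows, columns=["reaction_id", "flux", "is_reaction_of_interest"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def flux_snapshot_protocol(
    genotype: Genotype,
    model: StoichiometricModel,
    *,
    volume: float = 0.01,
    glucose_mmol_l: float = 0.1389,
    km: float = 0.01,
    dt: float = 1.0,
    cycles: int = 10,
    dilution_fraction: float = 0.01,
    founding_cells: int = 1_000_000,
    cell_mass: float = 6e-13,
    c_total: float | None = None,
    glucose_minute: float = 10.0,
    acetate_minute: float = 388.0,
    growth_update: str = "paper",
) -> tuple[FluxSnapshot, FluxSnapshot]:
    """Record a genotype's glucose- and acetate-phase flux maps.

    The genotype is grown alone (mutation off) through ``cycles`` daily
    1:100 transfer cycles in glucose medium so initial conditions wash
    out; on the final day the full flux vector is captured at
    ``glucose_minute`` (glucose phase; growth starts at minute 0 since
    the model has no lag) and at ``acetate_minute`` (acetate phase —
    meaningful only if the genotype consumes acetate then).
    """
    from . import fixtures

    resolve = fixtures.alias_resolver(model)
    glc, ac, o2 = resolve("glucose"), resolve("acetate"), resolve("oxygen")
    mutable = model.mutable_exchanges()
    budget = c_total if c_total is not None else sum(genotype.v_max.values())
    solver = BudgetedFBASolver(model, mutable, budget)

    tracked = [ex for ex in mutable if ex != o2]
    fresh = {ex: glucose_mmol_l if ex == glc else 0.0 for ex in tracked}
    env = Environment(dict(fresh), volume, non_depleting=frozenset({o2}))
    pops = PopulationState({genotype.genotype_id: founding_cells * cell_mass}, cell_mass)
    genotypes = {genotype.genotype_id: genotype}
    rng = np.random.default_rng(0)

    traj = None
    for day in range(1, cycles + 1):
        record = day == cycles
        traj, env, pops = run_cycle(
            env, pops, genotypes, solver,
            dt=dt, km=km, growth_update=growth_update,
            record_exchange_fluxes=record, record_full_fluxes=record,
        )
        if day == 1 and pops.biomass[genotype.genotype_id] <= founding_cells * cell_mass:
            raise NoGrowthError(
                f"genotype {genotype.genotype_id}: no growth under protocol"
            )
        if day < cycles:
            pops, env = dilute(pops, env, dilution_fraction, fresh, rng, deterministic=True)

    def capture(phase: str, minute: float) -> FluxSnapshot:
        idx = int(np.argmin(np.abs(np.asarray(traj.times) - minute)))
        flux_vec = traj.full_fluxes[idx].get(genotype.genotype_id)
        mus = traj.growth_rates[idx]
        fluxes = (
            {r: 0.0 for r in model.reactions}
            if flux_vec is None
            else dict(zip(model.reactions, (float(v) for v in flux_vec)))
        )
        roi = {r: fluxes[r] for r in REACTIONS_OF_INTEREST if r in fluxes}
        return FluxSnapshot(
            genotype_id=genotype.genotype_id,
            phase=phase,
            minute=float(traj.times[idx]),
            growth_rate=float(mus.get(genotype.genotype_id, 0.0)),
            fluxes=fluxes,
            reactions_of_interest=roi,
        )

    return capture("glucose", glucose_minute), capture("acetate", acetate_minute)


def cycles_to_generations(cycles: int, dilution_fraction: float = 0.01) -> float:
    """Generations represented by ``cycles`` serial transfers.

    Each cycle regrows the population by 1/dilution_fraction, i.e.
    log2(1/fraction) doublings: 300 cycles at 1 % correspond to ~1993
    generations.
    """
    if not 0.0 < dilution_fraction < 1.0:
        raise ValueError("dilution_fraction must be in (0, 1)")
    return cycles * math.log2(1.0 / dilution_fraction)
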