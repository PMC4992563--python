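"""The serial-transfer evolution experiment.

Repeats daily batch-growth cycles with 1 % population bottlenecks and
99 %/1 % fresh/spent medium mixing, while the evolution engine introduces
uptake-capacity mutants, for a configured number of cycles.  Selection is
purely a consequence of differential growth; the dilution is a per-genotype
binomial draw, so drift at the bottleneck is real.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import (
    DEFAULT_CELL_MASS,
    CycleTrajectory,
    Environment,
    PopulationState,
    run_cycle,
)
from .evolution import EvolutionEngine, Genotype, GenotypeRegistry
from .solver import BudgetedFBASolver

__all__ = ["SimulationConfig", "ExperimentResult", "dilute", "run_experiment"]

log = logging.getLogger(__name__)


def version(package: str) -> str:
    try:
        return _pkg_version(package)
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


@dataclass
class SimulationConfig:
    """Parameters of one evoFBA experiment.

    Defaults reproduce the full-scale LTEE-style transfer protocol: a 10-ml
    batch reactor refilled daily with glucose at 0.1389 mmol/l, 24-h
    cycles at 1-min resolution, 1 % bottlenecks, a 40 mmol/gDW/h total
    uptake budget, the ancestor splitting it 10/10/20 over glucose,
    acetate and oxygen, mutations at 1e-6 per cell per generation with
    step sizes uniform on (-10, 10), and 550 cycles.

    Substrate keys in ``fresh_medium``, ``initial_v_max`` and
    ``non_depleting`` may be common names (``glucose``) or exchange ids
    (``EX_glc__D_e``); they are resolved against the model's alias table.
    """

    model: str = "ecoli_core"
    cycles: int = 550
    cycle_hours: float = 24.0
    dt_min: float = 1.0
    volume: float = 0.01
    dilution_fraction: float = 0.01
    fresh_medium: dict[str, float] = field(default_factory=lambda: {"glucose": 0.1389})
    c_total: float = 40.0
    initial_v_max: dict[str, float] = field(
        default_factory=lambda: {"glucose": 10.0, "acetate": 10.0, "oxygen": 20.0}
    )
    km: float = 0.01
    mutation_rate: float = 1e-6
    mutation_step: float = 10.0
    cell_mass: float = DEFAULT_CELL_MASS
    seed: int = 0
    growth_update: str = "paper"
    founding_cells: int = 1_000_000
    non_depleting: list[str] = field(default_factory=lambda: ["oxygen"])
    deterministic_dilution: bool = False
    store_trajectories: list[int] = field(default_factory=list)
    checkpoint_every: int = 0

    def validate(self) -> None:
        if not 0.0 < self.dilution_fraction < 1.0:
            raise ValueError("dilution_fraction must be in (0, 1)")
        if self.volume <= 0 or self.c_total <= 0 or self.km <= 0:
            raise ValueError("volume, c_total and km must be positive")
        if self.growth_update not in {"paper", "exponential"}:
            raise ValueError("growth_update must be 'paper' or 'exponential'")
        total = sum(self.initial_v_max.values())
        if abs(total - self.c_total) > 1e-9:
            raise ValueError(
                f"uptake budget violated: initial v_max sums to {total}, "
                f"expected c_total = {self.c_total}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentResult:
    """Everything a simulation produced.

    Cell counts are absolute cells, medium concentrations mmol/l, v_max
    entries mmol/gDW/h.  ``pre_dilution_cells[c]`` / ``post_dilution_cells[c]``
    are sparse genotype -> cells maps for cycle c+1; ``end_medium[c]`` is
    the spent medium at the end of that cycle (before mixing).
    """

    config: SimulationConfig
    registry: GenotypeRegistry
    pre_dilution_cells: list[dict[int, int]]
    post_dilution_cells: list[dict[int, int]]
    end_medium: list[dict[str, float]]
    trajectories: dict[int, CycleTrajectory] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def peak_cells(self, genotype_id: int) -> int:
        peak = 0
        for record in (self.pre_dilution_cells, self.post_dilution_cells):
            for counts in record:
                peak = max(peak, counts.get(genotype_id, 0))
        return peak

    def final_population(self) -> dict[int, int]:
        return dict(self.post_dilution_cells[-1]) if self.post_dilution_cells else {}

    def counts_frame(self, post: bool = True) -> pd.DataFrame:
        rows = []
        record = self.post_dilution_cells if post else self.pre_dilution_cells
        for cycle, counts in enumerate(record, start=1):
            for g, n in sorted(counts.items()):
                rows.append((cycle, g, n))
        return pd.DataFrame(rows, columns=["cycle", "genotype_id", "cells"])

    def medium_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.end_medium)
        df.insert(0, "cycle", range(1, len(self.end_medium) + 1))
        return df

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.registry.write_jsonl(out / "registry.jsonl")
        self.counts_frame(post=True).to_csv(out / "survivors.tsv", sep="\t", index=False)
        self.medium_frame().to_csv(out / "medium.tsv", sep="\t", index=False)
        with open(out / "metadata.json", "w") as fh:
            json.dump(self.metadata, fh, indent=2, default=str)
        for cycle, traj in self.trajectories.items():
            traj.to_tsv(out / f"trajectory_cycle{cycle}.tsv")


def dilute(
    pops: PopulationState,
    env: Environment,
    fraction: float,
    fresh_medium: dict[str, float],
    rng: np.random.Generator,
    *,
    deterministic: bool = False,
) -> tuple[PopulationState, Environment]:
    """Serial transfer: sample cells and mix fresh with spent medium.

    Each genotype's survivor count is Binomial(N_i, fraction) (or
    round(N_i * fraction) in deterministic mode); survivors set the new
    biomass at one cell mass each, and genotypes drawn to zero go
    extinct.  The next cycle's medium is (1 - fraction) * fresh +
    fraction * spent for every tracked substrate, so secreted byproducts
    carry over at the transfer fraction.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    new_biomass: dict[int, float] = {}
    for g, bm in pops.biomass.items():
        n = int(bm / pops.cell_mass)
        if n < 1:
            continue
        k = int(round(n * fraction)) if deterministic else int(rng.binomial(n, fraction))
        if k >= 1:
            new_biomass[g] = k * pops.cell_mass
    new_pops = PopulationState(new_biomass, pops.cell_mass)

    substrates = set(env.concentrations) | set(fresh_medium)
    new_conc = {
        s: (1.0 - fraction) * fresh_medium.get(s, 0.0)
        + fraction * env.concentrations.get(s, 0.0)
        for s in substrates
    }
    return new_pops, Environment(new_conc, env.volume, env.non_depleting)


def _resolved(config: SimulationConfig):
    """Model plus config substrate keys resolved to exchange ids."""
    from . import fixtures

    model = fixtures.get_model(config.model)
    resolve = fixtures.alias_resolver(model)
    initial_v_max = {resolve(k): v for k, v in config.initial_v_max.items()}
    fresh = {resolve(k): v for k, v in config.fresh_medium.items()}
    non_depleting = frozenset(resolve(k) for k in config.non_depleting)

    mutable = model.mutable_exchanges()
    unknown = set(initial_v_max) - set(mutable)
    if unknown:
        raise ValueError(f"initial v_max names non-mutable exchanges: {sorted(unknown)}")
    full_v_max = {ex: initial_v_max.get(ex, 0.0) for ex in mutable}
    tracked = [ex for ex in mutable if ex not in non_depleting]
    return model, mutable, full_v_max, fresh, non_depleting, tracked


def run_experiment(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Run the full evoFBA experiment described by ``config``.

    Deterministic given (config, seed): a single seeded generator drives
    mutation and dilution draws.  The founding population runs one
    un-evolved burn-in cycle (cycle 0) and is diluted once, so cycle 1
    starts from a steady transfer regime; the burn-in is not recorded.
    """
    config.validate()
    model, mutable, v_max0, fresh, non_depleting, tracked = _resolved(config)
    solver = BudgetedFBASolver(model, mutable, config.c_total)
    rng = np.random.default_rng(config.seed)

    ancestor = Genotype(genotype_id=1, parent_id=None, v_max=v_max0, birth=(0, 0))
    ancestor.validate(config.c_total)
    registry = GenotypeRegistry(ancestor)
    genotypes: dict[int, Genotype] = {1: ancestor}

    fresh_full = {ex: fresh.get(ex, 0.0) for ex in tracked}
    env = Environment(dict(fresh_full), config.volume, non_depleting)
    pops = PopulationState(
        {1: config.founding_cells * config.cell_mass}, config.cell_mass
    )

    engine = EvolutionEngine(
        registry,
        genotypes,
        rng,
        mutation_rate=config.mutation_rate,
        step_bound=config.mutation_step,
        c_total=config.c_total,
        dt=config.dt_min,
    )

    def one_cycle(evolve: bool, record: bool):
        nonlocal env, pops
        traj, env, pops = run_cycle(
            env,
            pops,
            genotypes,
            solver,
            hours=config.cycle_hours,
            dt=config.dt_min,
            km=config.km,
            growth_update=config.growth_update,
            record_exchange_fluxes=record,
            on_step=engine if evolve and config.mutation_rate > 0 else None,
        )
        return traj

    # burn-in cycle 0: establish the steady transfer regime, discard
    one_cycle(evolve=False, record=False)
    pops, env = dilute(
        pops, env, config.dilution_fraction, fresh_full, rng,
        deterministic=config.deterministic_dilution,
    )

    pre_counts: list[dict[int, int]] = []
    post_counts: list[dict[int, int]] = []
    end_medium: list[dict[str, float]] = []
    trajectories: dict[int, CycleTrajectory] = {}

    result = ExperimentResult(
        config=config,
        registry=registry,
        pre_dilution_cells=pre_counts,
        post_dilution_cells=post_counts,
        end_medium=end_medium,
        trajectories=trajectories,
        metadata={
            "seed": config.seed,
            "model_id": model.model_id,
            "mutable_exchanges": mutable,
            "config": config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
            ).hexdigest(),
            "evofba_version": version("evofba"),
        },
    )

    for cycle in range(1, config.cycles + 1):
        engine.cycle = cycle
        traj = one_cycle(evolve=True, record=cycle in config.store_trajectories)
        if cycle in config.store_trajectories:
            trajectories[cycle] = traj
        pre = pops.cell_counts()
        pre_counts.append({g: n for g, n in pre.items() if n > 0})
        end_medium.append(dict(env.concentrations))
        pops, env = dilute(
            pops, env, config.dilution_fraction, fresh_full, rng,
            deterministic=config.deterministic_dilution,
        )
        post = pops.cell_counts()
        post_counts.append({g: n for g, n in post.items() if n > 0})
        if log.isEnabledFor(logging.INFO):
            glc_id = next((ex for ex in tracked if "glc" in ex), None)
            ac_id = next((ex for ex in tracked if ex.startswith("EX_ac")), None)
            log.info(
                "cycle %d: %d genotypes alive, %d cells, %d genotypes total, "
                "end-of-day glucose %.4g ac %.4g mmol/l",
                cycle,
                len(post_counts[-1]),
                sum(post_counts[-1].values()),
                len(registry),
                end_medium[-1].get(glc_id, float("nan")),
                end_medium[-1].get(ac_id, float("nan")),
            )
        if out_dir and config.checkpoint_every and cycle % config.checkpoint_every == 0:
            result.save(out_dir)

    if out_dir:
        result.save(out_dir)
    return result
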