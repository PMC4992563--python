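"""Survivor statistics, lineage graphs, diauxie, flux snapshots, generations."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import ANCESTOR_VMAX, full_vmax
from evofba import (
    Genotype,
    GenotypeRegistry,
    build_lineage_graph,
    cycles_to_generations,
    detect_diauxic_shift,
    flux_snapshot_protocol,
    survivors,
)
from evofba.analysis import NoGrowthError
from evofba.experiment import ExperimentResult, SimulationConfig


def synthetic_result(parents, post_counts, pre_counts=None):
    """Assemble an ExperimentResult from a parent map and count tables."""
    registry = GenotypeRegistry(Genotype(1, None, {"glc": 40.0}))
    for gid in sorted(parents):
        if gid == 1:
            continue
        registry.genotypes[gid] = Genotype(gid, parents[gid], {"glc": 40.0})
    registry._next_id = max(parents) + 1
    return ExperimentResult(
        config=SimulationConfig(),
        registry=registry,
        pre_dilution_cells=pre_counts or post_counts,
        post_dilution_cells=post_counts,
        end_medium=[{} for _ in post_counts],
    )


class TestSurvivors:
    def test_only_ancestor_in_mutation_off_run(self):
        res = synthetic_result({1: None}, [{1: 50}, {1: 40}])
        assert survivors(res, min_cycles=1) == [1]

    def test_genotype_extinct_at_first_dilution_excluded(self):
        res = synthetic_result({1: None, 2: 1}, [{1: 50}, {1: 40}])
        assert survivors(res, min_cycles=1) == [1]

    def test_matches_independent_tally(self):
        """Cross-check against a hand tally over the count table."""
        rng = np.random.default_rng(0)
        parents = {1: None, **{g: 1 for g in range(2, 12)}}
        counts = []
        for _ in range(20):
            counts.append(
                {g: int(rng.integers(0, 3)) for g in parents if rng.random() < 0.7}
            )
        res = synthetic_result(parents, counts)
        for min_cycles in (1, 3, 5):
            expected = sorted(
                g
                for g in parents
                if sum(1 for c in counts if c.get(g, 0) >= 1) >= min_cycles
            )
            assert survivors(res, min_cycles=min_cycles) == expected


class TestLineageGraph:
    def test_threshold_zero_is_identity_chain(self):
        res = synthetic_result({1: None, 2: 1, 3: 2}, [{1: 5, 2: 5, 3: 5}])
        g = build_lineage_graph(res, min_peak_cells=0, annotate=())
        assert sorted(g.edges) == [(1, 2), (2, 3)]

    def test_contraction_skips_unretained_intermediate(self):
        res = synthetic_result({1: None, 2: 1, 3: 2}, [{1: 50, 2: 1, 3: 50}])
        g = build_lineage_graph(res, min_peak_cells=10, annotate=())
        assert sorted(g.nodes) == [1, 3]
        assert list(g.edges) == [(1, 3)]

    def test_ancestor_always_retained_as_root(self):
        res = synthetic_result({1: None, 2: 1}, [{2: 100}])
        g = build_lineage_graph(res, min_peak_cells=10, annotate=())
        assert 1 in g.nodes
        assert nx.is_arborescence(g) or g.number_of_nodes() == 1

    def test_orphan_parent_is_data_integrity_error(self):
        res = synthetic_result({1: None, 3: 2}, [{1: 5, 3: 5}])  # 2 missing
        with pytest.raises(ValueError, match="orphan"):
            build_lineage_graph(res, min_peak_cells=0)

    def test_contraction_preserves_reachability_vs_bruteforce(self):
        """On random registries (<= 50 genotypes), retained node u reaches
        retained v in the contracted graph iff it does in the full tree
        (brute-force transitive closure oracle)."""
        rng = np.random.default_rng(99)
        for _ in range(10):
            n = int(rng.integers(5, 50))
            parents = {1: None}
            for g in range(2, n + 1):
                parents[g] = int(rng.integers(1, g))
            counts = [{g: int(rng.integers(0, 100)) for g in parents}]
            res = synthetic_result(parents, counts)
            graph = build_lineage_graph(res, min_peak_cells=50, annotate=())

            full = nx.DiGraph(
                (p, c) for c, p in parents.items() if p is not None
            )
            closure = nx.transitive_closure(full, reflexive=False)
            retained = set(graph.nodes)
            contracted_closure = nx.transitive_closure(graph, reflexive=False)
            for u, v in itertools.permutations(retained, 2):
                assert contracted_closure.has_edge(u, v) == closure.has_edge(u, v)

    def test_relative_uptake_annotations(self):
        res = synthetic_result({1: None}, [{1: 10}])
        res.registry.genotypes[1] = Genotype(
            1, None, {"EX_glc__D_e": 10.0, "EX_ac_e": 10.0, "EX_o2_e": 20.0}
        )
        g = build_lineage_graph(res, min_peak_cells=0)
        assert g.nodes[1]["rel_vmax_EX_glc__D_e"] == pytest.approx(0.25)
        assert g.nodes[1]["rel_vmax_EX_o2_e"] == pytest.approx(0.5)


class TestDiauxicShift:
    def test_ancestor_switches_to_acetate_consumption(self, ancestor_day):
        """The ancestor secretes acetate during the glucose phase, then
        switches to net acetate uptake and oxidation."""
        traj, _, _ = ancestor_day
        shift = detect_diauxic_shift(traj, 1)
        assert shift is not None
        ac = traj.genotype_exchange_series(1, "EX_ac_e")
        before = ac[: traj.times.index(shift)]
        assert before.min() < -1e-6  # secretion phase precedes the switch

    def test_shift_invariant_to_biomass_rescaling(self, core_model, core_solver, ancestor):
        """Scaling the founding biomass shifts timing but the detector
        still finds a switch with the same medium-trajectory shape."""
        from conftest import CELL_MASS, fresh_environment
        from evofba import PopulationState, run_cycle

        shifts = []
        for cells in (1_000_000, 4_000_000):
            env = fresh_environment(core_model, volume=0.01)
            pops = PopulationState({1: cells * CELL_MASS}, CELL_MASS)
            traj, _, _ = run_cycle(
                env, pops, {1: ancestor}, core_solver, record_exchange_fluxes=True
            )
            shifts.append(detect_diauxic_shift(traj, 1))
        assert None not in shifts
        assert shifts[1] < shifts[0]  # more biomass, earlier switch

    def test_zero_acetate_capacity_has_no_shift(self, core_model, core_solver):
        """An evolved glucose specialist (acetate v_max 0) never consumes
        acetate: no shift."""
        from conftest import CELL_MASS, fresh_environment
        from evofba import PopulationState, run_cycle

        glc_spec = Genotype(
            2, 1, full_vmax(core_model, {"EX_glc__D_e": 20.0, "EX_o2_e": 20.0})
        )
        env = fresh_environment(core_model, volume=0.01)
        pops = PopulationState({2: 1_000_000 * CELL_MASS}, CELL_MASS)
        traj, _, _ = run_cycle(
            env, pops, {2: glc_spec}, core_solver, record_exchange_fluxes=True
        )
        assert detect_diauxic_shift(traj, 2) is None

    def test_flat_trajectory_has_no_shift(self, toy_model, toy_solver, toy_ancestor):
        from conftest import CELL_MASS, fresh_environment
        from evofba import PopulationState, run_cycle

        env = fresh_environment(toy_model, volume=1e-6, glucose=0.0)
        pops = PopulationState({1: 1000 * CELL_MASS}, CELL_MASS)
        traj, _, _ = run_cycle(
            env, pops, {1: toy_ancestor}, toy_solver, hours=2.0, dt=5.0,
            record_exchange_fluxes=True,
        )
        assert detect_diauxic_shift(
            traj, 1, glucose_exchange="EX_glc", acetate_exchange="EX_ac"
        ) is None


class TestFluxSnapshots:
    def test_ancestor_glucose_phase(self, core_model, ancestor):
        """Minute 10 of the final day: glycolytic flux forward (PGI > 0),
        acetate secreted, no glyoxylate shunt."""
        glc_snap, _ = flux_snapshot_protocol(ancestor, core_model)
        assert glc_snap.growth_rate > 0.5
        assert glc_snap.reactions_of_interest["PGI"] > 1.0
        assert glc_snap.fluxes["EX_ac_e"] > 1e-6  # raw sign: secretion
        assert glc_snap.reactions_of_interest["MALS"] == pytest.approx(0.0, abs=1e-9)

    def test_acetate_specialist_acetate_phase_uses_glyoxylate_shunt(self, core_model):
        """A genotype with high acetate and low oxygen capacity exhausts
        glucose early and grows on its own acetate at the default
        388-minute capture: glyoxylate shunt on, glycolysis reversed."""
        specialist = Genotype(
            44490, 1,
            full_vmax(core_model, {"EX_glc__D_e": 10.0, "EX_ac_e": 20.0, "EX_o2_e": 10.0}),
        )
        glc_snap, ac_snap = flux_snapshot_protocol(specialist, core_model)
        assert glc_snap.reactions_of_interest["MALS"] == pytest.approx(0.0, abs=1e-9)
        assert ac_snap.growth_rate > 0.0
        assert ac_snap.fluxes["EX_ac_e"] < -1.0  # raw sign: uptake
        assert ac_snap.reactions_of_interest["MALS"] > 0.1
        assert ac_snap.reactions_of_interest["PGI"] < 0.0  # gluconeogenic

    def test_snapshots_satisfy_steady_state(self, core_model, ancestor):
        glc_snap, ac_snap = flux_snapshot_protocol(ancestor, core_model)
        for snap in (glc_snap, ac_snap):
            v = np.array([snap.fluxes[r] for r in core_model.reactions])
            assert np.abs(core_model.stoichiometry @ v).max() < 1e-6

    def test_nongrowing_genotype_raises(self, core_model):
        dead = Genotype(9, 1, full_vmax(core_model, {"EX_o2_e": 40.0}))
        with pytest.raises(NoGrowthError):
            flux_snapshot_protocol(dead, core_model)


class TestGenerations:
    def test_paper_anchor(self):
        """300 one-percent transfer cycles are ~2000 generations."""
        assert cycles_to_generations(300, 0.01) == pytest.approx(1993.2, abs=0.1)

    def test_zero_cycles(self):
        assert cycles_to_generations(0, 0.01) == 0.0

    def test_full_protocol(self):
        assert cycles_to_generations(550, 0.01) == pytest.approx(3654.2, abs=0.1)

    def test_domain(self):
        with pytest.raises(ValueError):
            cycles_to_generations(10, 1.5)
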