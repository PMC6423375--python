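"""Cell agents on the lattice: placement, the five fate actions, decision
windows, occupancy and conservation invariants."""

import numpy as np
import pytest

from boolcell import (
    CellStatus,
    FateAction,
    MutationProfile,
    NetworkModel,
    SimulationConfig,
    make_toy_network,
    minifate_clone_panel,
)
from boolcell.errors import CapacityError
from boolcell.network import BooleanRule, NodeKind, NodeSpec
from boolcell.population import World, clone_counts, neighbor_offsets

from conftest import constrained  # noqa: F401  (re-exported fixture helpers)


def quiet_network():
    """A single self-maintaining gene: no fate nodes, nothing ever happens."""
    return NetworkModel(
        nodes=[NodeSpec(id="G", kind=NodeKind.GENE, rule=BooleanRule.identity("G"))],
        edges=[],
    )


def arrest_network():
    """Growth arrest permanently demanded; a toggle-like oscillator gene
    tracks whether the network is being updated."""
    return NetworkModel(
        nodes=[
            NodeSpec(id="Osc", kind=NodeKind.GENE, rule=BooleanRule.from_expression("!Osc")),
            NodeSpec(
                id="GrowthArrest",
                kind=NodeKind.FATE,
                fate_action=FateAction.GROWTH_ARREST,
                rule=BooleanRule.constant(1),
            ),
        ],
        edges=[],
    )


def make_world(network, n_cells, dims=(9, 9, 9), seed=0, profiles=None, **overrides):
    cfg = SimulationConfig(
        network=network,
        profiles=profiles or [],
        initial_cells=n_cells,
        lattice_dims=dims,
        max_steps=overrides.pop("max_steps", 500),
        decision_window=overrides.pop("decision_window", 10),
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return World(cfg, np.random.default_rng(seed))


class TestPlacement:
    def test_single_cell_at_exact_center(self):
        w = make_world(quiet_network(), 1)
        assert tuple(w.pos[0]) == (4, 4, 4)

    def test_seven_cells_fill_center_plus_face_shell(self):
        w = make_world(quiet_network(), 7)
        positions = {tuple(p) for p in w.pos[:7]}
        center = np.array([4, 4, 4])
        assert tuple(center) in positions
        others = [p for p in positions if p != tuple(center)]
        assert len(others) == 6
        for p in others:
            assert np.abs(np.array(p) - center).sum() == 1  # face neighbors

    def test_clone_counts_largest_remainder(self):
        counts = clone_counts([1 / 8] * 8, 100)
        assert sum(counts) == 100
        assert sorted(counts) == [12, 12, 12, 12, 13, 13, 13, 13]

    def test_equal_parts_panel_assignment(self):
        w = make_world(
            make_toy_network("minifate"),
            100,
            dims=(11, 11, 11),
            profiles=minifate_clone_panel(),
        )
        per_clone = np.bincount(w.clone[:100], minlength=8)
        assert sorted(per_clone.tolist()) == [12, 12, 12, 12, 13, 13, 13, 13]

    def test_capacity_error(self):
        with pytest.raises(Exception):
            make_world(quiet_network(), 30, dims=(3, 3, 3))

    def test_zero_cells_allowed(self):
        w = make_world(quiet_network(), 0)
        assert w.n_living == 0


class TestNeighborhoods:
    def test_moore_counts(self):
        assert len(neighbor_offsets(3, "moore")) == 26
        assert len(neighbor_offsets(2, "moore")) == 8

    def test_von_neumann_counts(self):
        assert len(neighbor_offsets(3, "von_neumann")) == 6
        assert len(neighbor_offsets(2, "von_neumann")) == 4


class TestProliferation:
    def test_isolated_cell_daughter_uniform_over_moore_neighbors(self):
        targets = set()
        for seed in range(120):
            w = make_world(quiet_network(), 1, seed=seed)
            daughter = w.act_proliferate(0)
            assert daughter is not None
            offset = tuple(w.pos[daughter] - w.pos[0])
            assert max(abs(o) for o in offset) == 1
            targets.add(offset)
        assert len(targets) == 26  # every Moore neighbor reachable over seeds

    def test_population_increases_by_exactly_one(self):
        w = make_world(quiet_network(), 5)
        before = w.n_living
        w.act_proliferate(0)
        assert w.n_living == before + 1

    def test_fully_enclosed_cell_enters_arrest(self):
        w = make_world(quiet_network(), 27, dims=(3, 3, 3))
        center_row = int(w.lattice.occupancy[1, 1, 1])
        result = w.act_proliferate(center_row)
        assert result is None
        assert w.status[center_row] == CellStatus.ARRESTED
        assert w.arrest_rounds[center_row] == 3

    def test_daughter_inherits_clone_and_state(self):
        net = make_toy_network("minifate")
        panel = [p for p in minifate_clone_panel() if p.clone_label == "EGFR+PTEN-"]
        panel[0].initial_fraction = 1.0
        w = make_world(net, 1, profiles=panel)
        parent_state = w.S[0].copy()
        daughter = w.act_proliferate(0)
        assert w.clone[daughter] == w.clone[0]
        # identical except the reset proliferation node
        pro = w.node_index["Proliferation"]
        assert w.S[daughter, pro] == 0
        assert w.S[0, pro] == 0
        mask = np.ones(w.n_nodes, dtype=bool)
        mask[pro] = False
        assert np.array_equal(w.S[daughter][mask], parent_state[mask])


class TestDeathActions:
    def test_apoptosis_removes_and_frees_slot(self):
        w = make_world(quiet_network(), 2)
        pos = tuple(w.pos[0])
        before = w.n_living
        w.act_apoptosis(0)
        assert w.n_living == before - 1
        assert w.lattice.is_free(pos)

    def test_freed_slot_reusable(self):
        w = make_world(quiet_network(), 7)
        # kill a face neighbor of the center, then let the center divide into it
        center_row = int(w.lattice.occupancy[4, 4, 4])
        victim = next(r for r in range(7) if r != center_row)
        vpos = tuple(w.pos[victim])
        w.act_apoptosis(victim)
        w.rng = np.random.default_rng(0)
        # daughter placement can reuse the freed slot
        free = w.lattice.free_neighbors(w.pos[center_row], w.offsets)
        assert vpos in free

    def test_necrotic_cell_keeps_slot_and_never_acts(self):
        w = make_world(quiet_network(), 2)
        pos = tuple(w.pos[0])
        w.act_necrosis(0)
        assert not w.lattice.is_free(pos)
        assert w.status[0] == CellStatus.NECROTIC
        state = w.S[0].copy()
        for _ in range(30):
            w.tick()
        assert w.status[0] == CellStatus.NECROTIC
        assert np.array_equal(w.S[0], state)
        # living count dropped by one, total occupancy unchanged
        assert w.n_living == 1
        assert (w.lattice.occupancy != -1).sum() == 2


class TestGrowthArrest:
    def test_network_paused_and_resumes_after_three_windows(self):
        w = make_world(arrest_network(), 1, decision_window=5, max_steps=200)
        # run to the first window boundary: the constant-1 arrest demand fires
        for _ in range(5):
            w.tick()
        assert w.status[0] == CellStatus.ARRESTED
        frozen = w.S[0].copy()
        entered = w.step
        # during the pause the oscillator gene must not advance
        while w.status[0] == CellStatus.ARRESTED and w.step < 100:
            w.tick()
            if w.status[0] == CellStatus.ARRESTED:
                assert np.array_equal(w.S[0], frozen)
        released = w.step
        assert released - entered == 3 * 5  # three decision rounds

    def test_consumption_multiplier_during_pause(self):
        w = make_world(arrest_network(), 1, decision_window=5)
        for _ in range(5):
            w.tick()
        assert w.cell(0).status == CellStatus.ARRESTED
        assert w.cell(0).consumption_multiplier == 0.5


class TestTick:
    def test_deferred_fates_only_at_window_boundary(self):
        net = make_toy_network("minifate")
        panel = [p for p in minifate_clone_panel() if p.clone_label == "EGFR+PTEN-"]
        panel[0].initial_fraction = 1.0
        w = make_world(net, 1, profiles=panel, decision_window=100, max_steps=300)
        for _ in range(99):
            w.tick()
        assert w.n_living == 1  # step 99: no proliferation yet
        w.tick()
        assert w.step == 100 and w.n_living == 2  # executed at the boundary

    def test_update_rate_one_is_single_node_attempt(self):
        net = make_toy_network("toggle")
        w = make_world(net, 3, decision_window=50)
        before = w.S[:3].copy()
        w.tick()
        diff = (w.S[:3] != before).sum(axis=1)
        assert (diff <= 1).all()

    def test_same_seed_identical_event_log(self):
        net = make_toy_network("minifate")
        logs = []
        for _ in range(2):
            w = make_world(net, 20, profiles=minifate_clone_panel(), seed=42,
                           decision_window=20, max_steps=150)
            w.run()
            logs.append(list(w.events))
        assert logs[0] == logs[1]

    def test_invariants_every_tick(self):
        net = make_toy_network("minifate")
        w = make_world(net, 30, profiles=minifate_clone_panel(), seed=3,
                       decision_window=10, max_steps=120, dims=(13, 13, 13))
        while w.step < 120 and w.n_living > 0:
            w.tick()
            w.check_invariants()

    def test_population_conservation_against_event_log(self):
        """living(t+1) - living(t) = births - apoptoses - necroses at t+1."""
        net = make_toy_network("minifate")
        w = make_world(net, 30, profiles=minifate_clone_panel(), seed=7,
                       decision_window=10, max_steps=100, dims=(13, 13, 13))
        living = [w.n_living]
        while w.step < 100 and w.n_living > 0:
            w.tick()
            living.append(w.n_living)
        import pandas as pd

        ev = pd.DataFrame(w.events, columns=["step", "cell", "clone", "event", "i", "j", "k"])
        for t in range(1, len(living)):
            births = ((ev.step == t) & (ev.event == "birth")).sum()
            deaths = ((ev.step == t) & ev.event.isin(["apoptosis", "necrosis"])).sum()
            assert living[t] - living[t - 1] == births - deaths

    def test_filled_lattice_reaches_zero_proliferation(self):
        """Spatial constraint: growth on a bounded lattice must stall."""
        net = make_toy_network("minifate")
        panel = [p for p in minifate_clone_panel() if p.clone_label == "EGFR+PTEN-"]
        panel[0].initial_fraction = 1.0
        w = make_world(net, 5, profiles=panel, dims=(5, 5, 5),
                       decision_window=5, max_steps=400)
        w.run()
        import pandas as pd

        ev = pd.DataFrame(w.events, columns=["step", "cell", "clone", "event", "i", "j", "k"])
        last_quarter = ev[ev.step > 300]
        assert (last_quarter.event == "birth").sum() == 0

    def test_world_of_only_necrotic_cells_is_fixed(self):
        w = make_world(quiet_network(), 4)
        for row in range(4):
            w.act_necrosis(row)
        snapshot = (w.S[:4].copy(), w.status[:4].copy(), w.pos[:4].copy())
        for _ in range(20):
            w.tick()
        assert np.array_equal(w.S[:4], snapshot[0])
        assert np.array_equal(w.status[:4], snapshot[1])
        assert np.array_equal(w.pos[:4], snapshot[2])
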