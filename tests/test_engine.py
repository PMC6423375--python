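"""Asynchronous Boolean dynamics: unstable sets, single steps, exhaustive
stable-state enumeration against a brute-force oracle, window simulation and
stochastic fate profiles."""

import numpy as np
import pytest

from boolcell import (
    FateAction,
    async_step,
    fate_probability_profile,
    find_stable_states,
    make_toy_network,
    simulate_to_window,
    unstable_nodes,
)
from boolcell.engine import MAX_FREE_NODES_EXHAUSTIVE
from boolcell.errors import SizeError
from boolcell.network import (
    BooleanRule,
    NetworkModel,
    NodeKind,
    NodeSpec,
)

from conftest import brute_force_fixed_points, constrained


class TestUnstableNodes:
    def test_toggle_stable_state(self, toggle):
        assert unstable_nodes({"A": 1, "B": 0}, toggle) == set()

    def test_toggle_both_on_is_doubly_unstable(self, toggle):
        assert unstable_nodes({"A": 1, "B": 1}, toggle) == {"A", "B"}

    def test_identity_network_always_stable(self):
        nodes = [
            NodeSpec(id=f"n{i}", kind=NodeKind.GENE, rule=BooleanRule.identity(f"n{i}"))
            for i in range(4)
        ]
        net = NetworkModel(nodes=nodes, edges=[])
        for code in range(16):
            state = {f"n{i}": (code >> i) & 1 for i in range(4)}
            assert unstable_nodes(state, net) == set()

    def test_locked_node_never_unstable(self, minifate):
        cnet = constrained(minifate, {"EGFR": 1})
        # EGFR=1 disagrees with its rule (EGF=0) but is locked
        state = {n: 0 for n in minifate.node_ids}
        state["EGFR"] = 1
        assert "EGFR" not in unstable_nodes(state, cnet)

    def test_receptor_never_unstable(self, minifate):
        state = {n: 0 for n in minifate.node_ids}
        state["EGF"] = 1
        assert "EGF" not in unstable_nodes(state, minifate)


class TestAsyncStep:
    def test_stable_state_unchanged(self, toggle, rng):
        state = {"A": 1, "B": 0}
        assert async_step(state, toggle, rng) == state

    def test_flips_exactly_one_node(self, toggle, rng):
        outcomes = set()
        for seed in range(40):
            r = np.random.default_rng(seed)
            new = async_step({"A": 1, "B": 1}, toggle, r)
            hamming = sum(new[k] != v for k, v in {"A": 1, "B": 1}.items())
            assert hamming == 1
            outcomes.add((new["A"], new["B"]))
        # both single-flip successors occur over seeds
        assert outcomes == {(0, 1), (1, 0)}

    def test_hamming_distance_at_most_one(self, minifate, rng):
        state = {n: int(rng.integers(2)) for n in minifate.node_ids}
        for _ in range(50):
            new = async_step(state, minifate, rng)
            assert sum(new[k] != state[k] for k in state) <= 1
            state = new

    def test_locked_node_never_selected(self, minifate, rng):
        cnet = constrained(minifate, {"EGFR": 1})
        state = {n: 0 for n in minifate.node_ids}
        state["EGFR"] = 1
        for _ in range(30):
            state = async_step(state, cnet, rng)
            assert state["EGFR"] == 1


class TestFindStableStates:
    def test_toggle_fixed_points(self, toggle):
        states = find_stable_states(toggle)
        as_tuples = {(s["A"], s["B"]) for s in states}
        assert as_tuples == {(1, 0), (0, 1)}

    @pytest.mark.parametrize("name", ["toggle", "cascade", "minifate"])
    def test_matches_brute_force_oracle(self, name):
        net = make_toy_network(name)
        ours = {
            tuple(s[n] for n in net.node_ids)
            for s in find_stable_states(net)
        }
        assert ours == brute_force_fixed_points(net)

    def test_minifate_all_clones_match_oracle(self, minifate, clone_panel):
        for label, profile in clone_panel.items():
            locks = {
                k: c.locked_value for k, c in profile.constraints.items()
            }
            cnet = constrained(minifate, profile)
            ours = {
                tuple(s[n] for n in minifate.node_ids)
                for s in find_stable_states(cnet, {"EGF": 0})
            }
            oracle = brute_force_fixed_points(minifate, locks, {"EGF": 0})
            assert ours == oracle, f"clone {label}"

    def test_minifate_wildtype_fates(self, minifate):
        states = find_stable_states(minifate, {"EGF": 0})
        assert len(states) == 2
        assert {s["PTEN"] for s in states} == {0, 1}
        for s in states:
            assert s["Apoptosis"] == 1
            assert s["Proliferation"] == 0
            assert s["GrowthArrest"] == 0

    def test_minifate_double_mutant_single_proliferative_state(
        self, minifate, clone_panel
    ):
        cnet = constrained(minifate, clone_panel["EGFR+PTEN-"])
        states = find_stable_states(cnet, {"EGF": 0})
        assert len(states) == 1
        assert states[0]["Proliferation"] == 1

    def test_refuses_oversized_state_space(self):
        n = MAX_FREE_NODES_EXHAUSTIVE + 1
        nodes = [
            NodeSpec(id=f"n{i}", kind=NodeKind.GENE, rule=BooleanRule.identity(f"n{i}"))
            for i in range(n)
        ]
        net = NetworkModel(nodes=nodes, edges=[])
        with pytest.raises(SizeError, match="free nodes"):
            find_stable_states(net)


class TestSimulateToWindow:
    def test_double_mutant_always_proliferates(self, minifate, clone_panel, rng):
        cnet = constrained(minifate, clone_panel["EGFR+PTEN-"])
        for _ in range(20):
            state = {n: int(rng.integers(2)) for n in minifate.node_ids}
            state.update({"EGF": 0, "EGFR": 1, "PTEN": 0})
            _, outcome = simulate_to_window(state, cnet, 100, rng)
            assert outcome.decision == FateAction.PROLIFERATION

    def test_wildtype_always_apoptoses(self, minifate, rng):
        for _ in range(20):
            state = {n: int(rng.integers(2)) for n in minifate.node_ids}
            state["EGF"] = 0
            _, outcome = simulate_to_window(state, minifate, 100, rng)
            assert outcome.decision == FateAction.APOPTOSIS
            assert outcome.step_of_decision is not None

    def test_tiny_window_reports_none(self, cascade, rng):
        # all-zero state: the proliferation node cannot activate in 1 step
        state = {n: 0 for n in cascade.node_ids}
        _, outcome = simulate_to_window(state, cascade, 1, rng)
        assert outcome.decision == FateAction.NONE
        assert outcome.step_of_decision is None

    def test_apoptosis_is_immediate_not_window_end(self, minifate):
        # a state where apoptosis is already rule-confirmed fires at step 0
        state = {n: 0 for n in minifate.node_ids}
        state.update({"P53": 1, "Apoptosis": 1})
        rng = np.random.default_rng(0)
        _, outcome = simulate_to_window(state, minifate, 100, rng)
        assert outcome.decision == FateAction.APOPTOSIS
        assert outcome.step_of_decision == 0


class TestFateProfile:
    def test_fractions_sum_to_one(self, minifate, clone_panel):
        res = fate_probability_profile(
            minifate, clone_panel["EGFR+"], n_cells=50, n_repeats=8, window=60, seed=9
        )
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_double_mutant_profile_certain(self, minifate, clone_panel):
        res = fate_probability_profile(
            minifate,
            clone_panel["EGFR+PTEN-"],
            n_cells=100,
            n_repeats=10,
            window=100,
            seed=2,
        )
        assert res.fractions["proliferation"] == pytest.approx(1.0)

    def test_egfr_single_mutant_splits_on_pten_initialization(
        self, minifate, clone_panel
    ):
        """PTEN is self-maintaining, so its random initial value (p=1/2)
        decides between proliferation and growth arrest."""
        res = fate_probability_profile(
            minifate, clone_panel["EGFR+"], n_cells=500, n_repeats=8, window=100, seed=4
        )
        se = max(res.se["proliferation"], 1e-4)
        assert abs(res.fractions["proliferation"] - 0.5) < 4 * se + 0.02
        assert abs(res.fractions["growth_arrest"] - 0.5) < 4 * se + 0.02

    def test_reproducible_with_same_seed(self, minifate, clone_panel):
        kwargs = dict(n_cells=40, n_repeats=4, window=50, seed=11)
        a = fate_probability_profile(minifate, clone_panel["EGFR+"], **kwargs)
        b = fate_probability_profile(minifate, clone_panel["EGFR+"], **kwargs)
        assert a.fractions == b.fractions
        assert np.array_equal(a.final_states, b.final_states)

    def test_unsatisfiable_fate_nodes_report_none(self):
        nodes = [
            NodeSpec(id="G", kind=NodeKind.GENE, rule=BooleanRule.identity("G")),
            NodeSpec(
                id="Proliferation",
                kind=NodeKind.FATE,
                fate_action=FateAction.PROLIFERATION,
                rule=BooleanRule.constant(0),
            ),
            NodeSpec(
                id="Apoptosis",
                kind=NodeKind.FATE,
                fate_action=FateAction.APOPTOSIS,
                rule=BooleanRule.constant(0),
            ),
        ]
        net = NetworkModel(nodes=nodes, edges=[])
        res = fate_probability_profile(net, n_cells=50, n_repeats=4, window=30, seed=1)
        assert res.fractions["none"] == pytest.approx(1.0)


def test_async_trajectory_only_halts_at_true_fixed_points(minifate, rng):
    """Simulated states with an empty unstable set are exactly the
    enumerated fixed points (oracle agreement along trajectories)."""
    fixed = {
        tuple(s[n] for n in minifate.node_ids)
        for s in find_stable_states(minifate, {"EGF": 0})
    }
    for _ in range(50):
        state = {n: int(rng.integers(2)) for n in minifate.node_ids}
        state["EGF"] = 0
        for _ in range(200):
            new = async_step(state, minifate, rng)
            if new == state:
                break
            state = new
        if not unstable_nodes(state, minifate):
            assert tuple(state[n] for n in minifate.node_ids) in fixed
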