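"""Asynchronous Boolean dynamics (Thomas scheme).

One update step picks uniformly at random among the *unstable* nodes — nodes
whose rule output disagrees with their current value — and flips exactly that
node.  Fixed points of this scheme are precisely the logical stable states.

Receptor nodes are pinned from outside (by the microenvironment between
syncs) and locked nodes (mutations) hold their forced value; neither ever
counts as unstable.

Fate decisions during a simulation window:

* apoptosis/necrosis fate nodes are *immediate*: the decision fires as soon
  as the node is active and its rule currently confirms the activation
  (value 1 and rule output 1), checked at initialization and after every
  step.  The rule-confirmation guard keeps a randomly initialized fate bit
  from killing a cell whose network is in the process of switching it off.
* proliferation/growth-arrest fate nodes are *deferred*: their level is read
  once, at the end of the decision window, with proliferation taking
  priority over growth arrest when both are active.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import SizeError
from .network import (
    ConstrainedNetwork,
    FateAction,
    NetworkModel,
    NodeKind,
)

MAX_FREE_NODES_EXHAUSTIVE = 22
_ENUM_CHUNK = 1 << 16


def _as_constrained(network) -> ConstrainedNetwork:
    if isinstance(network, ConstrainedNetwork):
        return network
    return ConstrainedNetwork(network=network)


@dataclass(frozen=True)
class FateOutcome:
    decision: FateAction
    step_of_decision: int | None = None

    def __post_init__(self):
        if (self.decision == FateAction.NONE) != (self.step_of_decision is None):
            raise ValueError("decision is none iff step_of_decision is absent")


class CompiledNetwork:
    """Array-compiled view of a constrained network.

    States are uint8 row vectors ordered like ``self.names``; all operations
    are vectorized over a population of states (rows).
    """

    def __init__(
        self,
        network: ConstrainedNetwork | NetworkModel,
        pinned_receptors: Mapping[str, int] | None = None,
    ):
        cnet = _as_constrained(network)
        net = cnet.network
        self.constrained = cnet
        self.names: list[str] = net.node_ids
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.names)}
        self.n = len(self.names)

        self.receptor_mask = np.zeros(self.n, dtype=bool)
        self.locked_mask = np.zeros(self.n, dtype=bool)
        self.locked_values = np.zeros(self.n, dtype=np.uint8)
        self.pinned_values = np.zeros(self.n, dtype=np.uint8)

        self.parents: list[np.ndarray] = []
        self.weights: list[np.ndarray] = []
        self.tables: list[np.ndarray] = []
        for spec in net.nodes:
            if spec.kind == NodeKind.RECEPTOR:
                self.receptor_mask[self.index[spec.id]] = True
                self.parents.append(np.empty(0, dtype=np.intp))
                self.weights.append(np.empty(0, dtype=np.int64))
                self.tables.append(np.zeros(1, dtype=np.uint8))
                continue
            rule = spec.rule
            p_idx = np.array([self.index[p] for p in rule.parents], dtype=np.intp)
            self.parents.append(p_idx)
            self.weights.append(1 << np.arange(len(p_idx), dtype=np.int64))
            self.tables.append(rule.table_array())

        for node_id, value in cnet.locks.items():
            j = self.index[node_id]
            self.locked_mask[j] = True
            self.locked_values[j] = value
        if pinned_receptors:
            for node_id, value in pinned_receptors.items():
                j = self.index[node_id]
                self.pinned_values[j] = value

        self.updatable_mask = ~(self.receptor_mask | self.locked_mask)
        self.free_idx = np.flatnonzero(self.updatable_mask)

        self.fate_idx: dict[FateAction, np.ndarray] = {}
        for action in FateAction:
            if action == FateAction.NONE:
                continue
            idx = [
                self.index[n.id]
                for n in net.fate_nodes
                if n.fate_action == action
            ]
            self.fate_idx[action] = np.array(idx, dtype=np.intp)

    # -- state helpers ---------------------------------------------------
    def state_to_array(self, state: Mapping[str, int]) -> np.ndarray:
        return np.array([state[n] & 1 for n in self.names], dtype=np.uint8)

    def array_to_state(self, arr: np.ndarray) -> dict[str, int]:
        return {n: int(arr[j]) for j, n in enumerate(self.names)}

    def random_states(self, m: int, rng: np.random.Generator) -> np.ndarray:
        """Random initialization: each free node independently active with
        p=0.5; receptors at their pinned value; locks overwrite."""
        S = rng.integers(0, 2, size=(m, self.n), dtype=np.uint8)
        self.apply_pins(S)
        return S

    def apply_pins(self, S: np.ndarray) -> None:
        S[:, self.receptor_mask] = self.pinned_values[self.receptor_mask]
        S[:, self.locked_mask] = self.locked_values[self.locked_mask]

    # -- dynamics --------------------------------------------------------
    def next_values(self, S: np.ndarray) -> np.ndarray:
        """Rule output for every node of every row (receptors and locks map
        to their held values, so they are never unstable)."""
        out = np.empty_like(S)
        for j in range(self.n):
            if self.receptor_mask[j]:
                out[:, j] = S[:, j]
            elif self.locked_mask[j]:
                out[:, j] = self.locked_values[j]
            else:
                p = self.parents[j]
                if len(p) == 0:
                    out[:, j] = self.tables[j][0]
                else:
                    idx = S[:, p].astype(np.int64) @ self.weights[j]
                    out[:, j] = self.tables[j][idx]
        return out

    def async_flip(
        self, S: np.ndarray, N: np.ndarray, rng: np.random.Generator,
        rows: np.ndarray | None = None,
    ) -> None:
        """Flip one uniformly chosen unstable node per row, in place.

        Rows with no unstable node are left unchanged.  ``rows`` restricts
        the update to a boolean row mask.
        """
        unstable = (N != S) & self.updatable_mask
        if rows is not None:
            unstable &= rows[:, None]
        counts = unstable.sum(axis=1)
        hot = counts > 0
        if not hot.any():
            return
        k = (rng.random(S.shape[0]) * counts).astype(np.int64) + 1
        cum = np.cumsum(unstable, axis=1)
        cols = np.argmax(cum == k[:, None], axis=1)
        r = np.flatnonzero(hot)
        S[r, cols[r]] = N[r, cols[r]]

    def immediate_fate(
        self, S: np.ndarray, N: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-row immediate decisions: apoptosis wins ties over
        network-driven necrosis.  Returns (apoptosis_mask, necrosis_mask)."""
        confirmed = (S == 1) & (N == 1)
        apo_idx = self.fate_idx[FateAction.APOPTOSIS]
        nec_idx = self.fate_idx[FateAction.NECROSIS]
        apo = (
            confirmed[:, apo_idx].any(axis=1)
            if len(apo_idx)
            else np.zeros(S.shape[0], dtype=bool)
        )
        nec = (
            confirmed[:, nec_idx].any(axis=1)
            if len(nec_idx)
            else np.zeros(S.shape[0], dtype=bool)
        )
        return apo, nec & ~apo

    def deferred_fate(self, S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Window-end decisions read the fate-node level; proliferation has
        priority over growth arrest."""
        pro_idx = self.fate_idx[FateAction.PROLIFERATION]
        ga_idx = self.fate_idx[FateAction.GROWTH_ARREST]
        pro = (
            (S[:, pro_idx] == 1).any(axis=1)
            if len(pro_idx)
            else np.zeros(S.shape[0], dtype=bool)
        )
        ga = (
            (S[:, ga_idx] == 1).any(axis=1)
            if len(ga_idx)
            else np.zeros(S.shape[0], dtype=bool)
        )
        return pro, ga & ~pro


# ---------------------------------------------------------------------------
# single-state operations (the readable reference surface)


def unstable_nodes(
    state: Mapping[str, int],
    network: ConstrainedNetwork | NetworkModel,
    pinned_receptors: Mapping[str, int] | None = None,
) -> set[str]:
    """Nodes whose rule output disagrees with the current value, excluding
    locked nodes and receptors."""
    cn = CompiledNetwork(network, pinned_receptors)
    S = cn.state_to_array(state)[None, :]
    N = cn.next_values(S)
    mask = (N[0] != S[0]) & cn.updatable_mask
    return {cn.names[j] for j in np.flatnonzero(mask)}


def async_step(
    state: Mapping[str, int],
    network: ConstrainedNetwork | NetworkModel,
    rng: np.random.Generator,
    pinned_receptors: Mapping[str, int] | None = None,
) -> dict[str, int]:
    """One asynchronous update: flips one uniformly chosen unstable node, or
    returns the state unchanged if it is a fixed point."""
    cn = CompiledNetwork(network, pinned_receptors)
    S = cn.state_to_array(state)[None, :]
    N = cn.next_values(S)
    cn.async_flip(S, N, rng)
    return cn.array_to_state(S[0])


def find_stable_states(
    network: ConstrainedNetwork | NetworkModel,
    pinned_receptors: Mapping[str, int] | None = None,
) -> list[dict[str, int]]:
    """Exhaustively enumerate the fixed points over all assignments of the
    free (unlocked, non-receptor) nodes.

    Unpinned receptors are held at 0.  Refuses when the free-node count
    exceeds ``MAX_FREE_NODES_EXHAUSTIVE``.
    """
    cn = CompiledNetwork(network, pinned_receptors)
    f = len(cn.free_idx)
    if f > MAX_FREE_NODES_EXHAUSTIVE:
        raise SizeError(
            f"{f} free nodes exceed the exhaustive-enumeration guard "
            f"({MAX_FREE_NODES_EXHAUSTIVE}); use sampling-based exploration "
            "instead"
        )
    total = 1 << f
    found: list[dict[str, int]] = []
    base = np.zeros(cn.n, dtype=np.uint8)
    base[cn.receptor_mask] = cn.pinned_values[cn.receptor_mask]
    base[cn.locked_mask] = cn.locked_values[cn.locked_mask]
    for start in range(0, total, _ENUM_CHUNK):
        stop = min(start + _ENUM_CHUNK, total)
        codes = np.arange(start, stop, dtype=np.int64)
        S = np.tile(base, (len(codes), 1))
        for bit, j in enumerate(cn.free_idx):
            S[:, j] = ((codes >> bit) & 1).astype(np.uint8)
        N = cn.next_values(S)
        stable = (N == S).all(axis=1)
        for row in np.flatnonzero(stable):
            found.append(cn.array_to_state(S[row]))
    return found


def simulate_to_window(
    state: Mapping[str, int],
    network: ConstrainedNetwork | NetworkModel,
    window: int,
    rng: np.random.Generator,
    pinned_receptors: Mapping[str, int] | None = None,
) -> tuple[dict[str, int], FateOutcome]:
    """Simulate up to ``window`` asynchronous steps, reporting the fate.

    Immediate fates (apoptosis/necrosis) stop the simulation at the step
    where they fire; deferred fates (proliferation/growth arrest) are read
    at the window end.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    cn = CompiledNetwork(network, pinned_receptors)
    S = cn.state_to_array(state)[None, :]
    cn.apply_pins(S)
    for step in range(window + 1):
        N = cn.next_values(S)
        apo, nec = cn.immediate_fate(S, N)
        if apo[0]:
            return cn.array_to_state(S[0]), FateOutcome(FateAction.APOPTOSIS, step)
        if nec[0]:
            return cn.array_to_state(S[0]), FateOutcome(FateAction.NECROSIS, step)
        if step == window:
            break
        cn.async_flip(S, N, rng)
    pro, ga = cn.deferred_fate(S)
    if pro[0]:
        outcome = FateOutcome(FateAction.PROLIFERATION, window)
    elif ga[0]:
        outcome = FateOutcome(FateAction.GROWTH_ARREST, window)
    else:
        outcome = FateOutcome(FateAction.NONE)
    return cn.array_to_state(S[0]), outcome


# ---------------------------------------------------------------------------
# stochastic fate-probability profiles


_DECISIONS = [
    FateAction.PROLIFERATION,
    FateAction.APOPTOSIS,
    FateAction.NECROSIS,
    FateAction.GROWTH_ARREST,
    FateAction.NONE,
]


@dataclass
class FateProfileResult:
    """Decision fractions over replicated populations of cells.

    ``fractions``/``se`` are means and standard errors over repeats and sum
    to 1 across decisions (including "none").  ``time_series`` holds, for
    each step of the window, the mean cumulative fraction of cells whose
    immediate fate had fired by that step (columns ordered as
    ``decisions``).  ``final_states`` is the cells-by-nodes 0/1 matrix of
    the last repeat, for heatmap export.
    """

    decisions: list[str]
    fractions: dict[str, float]
    se: dict[str, float]
    n_cells: int
    n_repeats: int
    time_series: np.ndarray
    node_names: list[str] = field(default_factory=list)
    final_states: np.ndarray | None = None


def simulate_population_window(
    cn: CompiledNetwork,
    S: np.ndarray,
    window: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window simulation of a cell population.

    Returns (decision codes per row indexing ``_DECISIONS``, step of
    decision or -1, cumulative immediate-decision counts per step with shape
    ``(window + 1, 2)`` for apoptosis/necrosis).
    """
    m = S.shape[0]
    decision = np.full(m, _DECISIONS.index(FateAction.NONE), dtype=np.int8)
    dstep = np.full(m, -1, dtype=np.int64)
    undecided = np.ones(m, dtype=bool)
    cum = np.zeros((window + 1, 2), dtype=np.int64)
    for step in range(window + 1):
        N = cn.next_values(S)
        apo, nec = cn.immediate_fate(S, N)
        apo &= undecided
        nec &= undecided
        decision[apo] = _DECISIONS.index(FateAction.APOPTOSIS)
        decision[nec] = _DECISIONS.index(FateAction.NECROSIS)
        dstep[apo | nec] = step
        undecided &= ~(apo | nec)
        cum[step, 0] = (decision == _DECISIONS.index(FateAction.APOPTOSIS)).sum()
        cum[step, 1] = (decision == _DECISIONS.index(FateAction.NECROSIS)).sum()
        if step == window:
            break
        if undecided.any():
            cn.async_flip(S, N, rng, rows=undecided)
    pro, ga = cn.deferred_fate(S)
    pro &= undecided
    ga &= undecided
    decision[pro] = _DECISIONS.index(FateAction.PROLIFERATION)
    decision[ga] = _DECISIONS.index(FateAction.GROWTH_ARREST)
    dstep[pro | ga] = window
    return decision, dstep, cum


def fate_probability_profile(
    network: NetworkModel,
    profile=None,
    pinned_receptors: Mapping[str, int] | None = None,
    n_cells: int = 100,
    n_repeats: int = 100,
    window: int = 100,
    seed: int = 0,
) -> FateProfileResult:
    """Decision fractions from replicated random-initialization simulations.

    Each cell's free nodes start uniformly at random, mutations overwrite the
    initialization, then the cell is simulated to the window.
    """
    from .network import MutationProfile, apply_mutation_profile

    if n_cells < 1 or n_repeats < 1:
        raise ValueError("n_cells and n_repeats must be >= 1")
    if profile is None:
        profile = MutationProfile(clone_label="WT")
    cnet = apply_mutation_profile(network, profile)
    cn = CompiledNetwork(cnet, pinned_receptors)
    rng = np.random.default_rng(seed)

    frac = np.zeros((n_repeats, len(_DECISIONS)))
    series = np.zeros((window + 1, 2))
    final_states = None
    for r in range(n_repeats):
        S = cn.random_states(n_cells, rng)
        decision, _, cum = simulate_population_window(cn, S, window, rng)
        frac[r] = np.bincount(decision, minlength=len(_DECISIONS)) / n_cells
        series += cum / n_cells
        final_states = S
    series /= n_repeats
    mean = frac.mean(axis=0)
    se = (
        frac.std(axis=0, ddof=1) / np.sqrt(n_repeats)
        if n_repeats > 1
        else np.full(len(_DECISIONS), np.nan)
    )
    labels = [d.value for d in _DECISIONS]
    return FateProfileResult(
        decisions=labels,
        fractions=dict(zip(labels, mean.tolist())),
        se=dict(zip(labels, se.tolist())),
        n_cells=n_cells,
        n_repeats=n_repeats,
        time_series=series,
        node_names=cn.names,
        final_states=final_states,
    )
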