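"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
import sympy

from boolcell import (
    MutationProfile,
    NodeKind,
    apply_mutation_profile,
    make_toy_network,
    minifate_clone_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toggle():
    return make_toy_network("toggle")


@pytest.fixture
def cascade():
    return make_toy_network("cascade")


@pytest.fixture
def minifate():
    return make_toy_network("minifate")


@pytest.fixture
def clone_panel():
    return {p.clone_label: p for p in minifate_clone_panel()}


# ---------------------------------------------------------------------------
# independent oracles


def sympy_rule_eval(expression: str, env: dict[str, int]) -> int:
    """Evaluate a rule expression through sympy's boolean algebra —
    independent of the package's own parser and truth tables."""
    expr = sympy.sympify(expression.replace("!", "~"), evaluate=False)
    subs = {sympy.Symbol(k): bool(v) for k, v in env.items()}
    return int(bool(expr.subs(subs)))


def brute_force_fixed_points(
    network,
    locks: dict[str, int] | None = None,
    pins: dict[str, int] | None = None,
) -> set[tuple[int, ...]]:
    """Enumerate fixed points by direct evaluation of every rule expression
    with sympy over all assignments of the free nodes.

    Returns value tuples ordered like ``network.node_ids``.
    """
    locks = locks or {}
    pins = pins or {}
    names = network.node_ids
    by_id = {n.id: n for n in network.nodes}
    free = [
        n
        for n in names
        if n not in locks and by_id[n].kind != NodeKind.RECEPTOR
    ]
    fixed = set()
    for combo in itertools.product((0, 1), repeat=len(free)):
        env = dict(zip(free, combo))
        for n, v in locks.items():
            env[n] = v
        for n in names:
            if by_id[n].kind == NodeKind.RECEPTOR:
                env[n] = pins.get(n, 0)
        stable = True
        for n in names:
            spec = by_id[n]
            if spec.kind == NodeKind.RECEPTOR or n in locks:
                continue
            nxt = sympy_rule_eval(spec.rule.to_expression(), env)
            if nxt != env[n]:
                stable = False
                break
        if stable:
            fixed.add(tuple(env[n] for n in names))
    return fixed


def constrained(network, profile_or_locks):
    """Convenience: build a ConstrainedNetwork from a lock dict or profile."""
    from boolcell import Constraint

    if isinstance(profile_or_locks, MutationProfile):
        profile = profile_or_locks
    else:
        profile = MutationProfile(
            clone_label="test",
            constraints={
                k: Constraint(locked_value=v)
                for k, v in profile_or_locks.items()
            },
        )
    return apply_mutation_profile(network, profile)
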