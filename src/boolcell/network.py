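"""Typed logical networks and mutation-profile constraints.

A network distinguishes four node kinds.  Genes carry rules and may have both
incoming and outgoing links; receptors are environment inputs (no rule, no
incoming links); output nodes feed substance production and fate nodes trigger
cellular actions (both are sinks: no outgoing links).

Mutations are modelled as constraints on nodes: a node can be locked
constitutively active/inactive, or its rule can be replaced wholesale.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from .errors import NetworkValidationError
from .rules import BooleanRule


class NodeKind(str, enum.Enum):
    GENE = "gene"
    RECEPTOR = "receptor"
    OUTPUT = "output"
    FATE = "fate"


class FateAction(str, enum.Enum):
    PROLIFERATION = "proliferation"
    APOPTOSIS = "apoptosis"
    NECROSIS = "necrosis"
    GROWTH_ARREST = "growth_arrest"
    NONE = "none"


class EdgeSign(str, enum.Enum):
    ACTIVATION = "activation"
    INHIBITION = "inhibition"


@dataclass(frozen=True)
class NodeSpec:
    id: str
    kind: NodeKind
    fate_action: FateAction = FateAction.NONE
    rule: BooleanRule | None = None

    def __post_init__(self):
        if (self.fate_action != FateAction.NONE) != (self.kind == NodeKind.FATE):
            raise NetworkValidationError(
                f"node {self.id!r}: fate_action must be set iff kind is fate"
            )
        if self.kind == NodeKind.RECEPTOR and self.rule is not None:
            raise NetworkValidationError(
                f"receptor {self.id!r} must not carry a rule"
            )


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: EdgeSign = EdgeSign.ACTIVATION


@dataclass
class NetworkModel:
    """A validated logical network.

    Edge signs are metadata for display and provenance; the dynamics are fully
    determined by the node rules.
    """

    nodes: list[NodeSpec]
    edges: list[Edge] = field(default_factory=list)
    name: str = "network"

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    def node(self, node_id: str) -> NodeSpec:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(node_id)

    def nodes_of_kind(self, kind: NodeKind) -> list[NodeSpec]:
        return [n for n in self.nodes if n.kind == kind]

    @property
    def receptors(self) -> list[NodeSpec]:
        return self.nodes_of_kind(NodeKind.RECEPTOR)

    @property
    def fate_nodes(self) -> list[NodeSpec]:
        return self.nodes_of_kind(NodeKind.FATE)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate node ids: {dupes}")
        idset = set(ids)
        by_id = {n.id: n for n in self.nodes}

        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in idset:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target} references unknown node "
                        f"{endpoint!r}"
                    )
            if by_id[e.target].kind == NodeKind.RECEPTOR:
                raise NetworkValidationError(
                    f"receptor {e.target!r} must not have incoming edges"
                )
            if by_id[e.source].kind in (NodeKind.OUTPUT, NodeKind.FATE):
                raise NetworkValidationError(
                    f"{by_id[e.source].kind.value} node {e.source!r} must not "
                    "have outgoing edges"
                )

        in_sources = {n.id: set() for n in self.nodes}
        for e in self.edges:
            in_sources[e.target].add(e.source)
        for n in self.nodes:
            if n.rule is None:
                continue
            for p in n.rule.parents:
                if p not in idset:
                    raise NetworkValidationError(
                        f"rule of {n.id!r} references unknown node {p!r}"
                    )
                # implicit self-parents (self-maintaining defaults) are
                # allowed without a drawn edge
                if p != n.id and p not in in_sources[n.id]:
                    raise NetworkValidationError(
                        f"rule of {n.id!r} uses parent {p!r} with no "
                        "corresponding edge"
                    )

    def with_rules(self, replacements: Mapping[str, BooleanRule]) -> "NetworkModel":
        """A copy of the network with some node rules substituted."""
        new_nodes = [
            replace(n, rule=replacements[n.id]) if n.id in replacements else n
            for n in self.nodes
        ]
        # a replacement rule may introduce parents the drawn graph lacks;
        # add the implied edges so the structural invariants keep holding
        new_edges = list(self.edges)
        present = {(e.source, e.target) for e in new_edges}
        for node_id, rule in replacements.items():
            for p in rule.parents:
                if p != node_id and (p, node_id) not in present:
                    new_edges.append(Edge(source=p, target=node_id))
                    present.add((p, node_id))
        return NetworkModel(nodes=new_nodes, edges=new_edges, name=self.name)


# ---------------------------------------------------------------------------
# mutation profiles


@dataclass(frozen=True)
class Constraint:
    """Either a lock (force_active/force_inactive) or a rule replacement."""

    locked_value: int | None = None  # 1, 0, or None when rule replacement
    rule: BooleanRule | None = None

    def __post_init__(self):
        if (self.locked_value is None) == (self.rule is None):
            raise NetworkValidationError(
                "constraint must be exactly one of lock or rule replacement"
            )


FORCE_ACTIVE = Constraint(locked_value=1)
FORCE_INACTIVE = Constraint(locked_value=0)


@dataclass
class MutationProfile:
    clone_label: str
    constraints: dict[str, Constraint] = field(default_factory=dict)
    initial_fraction: float = 0.0

    def validate_against(self, network: NetworkModel) -> None:
        ids = set(network.node_ids)
        for node_id in self.constraints:
            if node_id not in ids:
                raise NetworkValidationError(
                    f"profile {self.clone_label!r} constrains unknown node "
                    f"{node_id!r}"
                )


def validate_profiles(
    network: NetworkModel, profiles: Iterable[MutationProfile]
) -> None:
    total = 0.0
    for p in profiles:
        p.validate_against(network)
        total += p.initial_fraction
    if total > 1.0 + 1e-9:
        raise NetworkValidationError(
            f"initial fractions sum to {total:.4f} > 1"
        )


@dataclass
class ConstrainedNetwork:
    """A network together with the lock set induced by a mutation profile.

    The base network is never modified: rule replacements are applied to a
    copy, and locked nodes are recorded with their fixed values.
    """

    network: NetworkModel
    locks: dict[str, int] = field(default_factory=dict)
    clone_label: str = "WT"

    def is_locked(self, node_id: str) -> bool:
        return node_id in self.locks


def apply_mutation_profile(
    network: NetworkModel, profile: MutationProfile
) -> ConstrainedNetwork:
    """Apply a clone's constraints, returning the constrained view.

    Idempotent for force-constraints: applying the same profile to the result's
    network yields an identical lock set and rules.
    """
    profile.validate_against(network)
    locks: dict[str, int] = {}
    replacements: dict[str, BooleanRule] = {}
    for node_id, c in profile.constraints.items():
        node = network.node(node_id)
        if node.kind == NodeKind.RECEPTOR and c.rule is not None:
            raise NetworkValidationError(
                f"cannot replace the rule of receptor {node_id!r}"
            )
        if c.locked_value is not None:
            locks[node_id] = c.locked_value
        else:
            replacements[node_id] = c.rule
    net = network.with_rules(replacements) if replacements else network
    return ConstrainedNetwork(network=net, locks=locks, clone_label=profile.clone_label)
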