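"""Built-in toy networks and ready-to-run scenario configurations.

The toy networks are deliberately small stand-ins for a full signaling
network, with the same node taxonomy:

* ``toggle`` — the mutual-inhibition switch, A* = !B, B* = !A.
* ``cascade`` — a linear activation chain G1 -> ... -> G4 ending in a
  proliferation fate node.
* ``minifate`` — an 8-node caricature of growth-factor signaling: an EGF
  receptor feeds EGFR; AKT integrates EGFR with the PTEN brake; P53
  opposes AKT; three fate nodes read the pathway out (proliferation when
  AKT wins, apoptosis when P53 is active without EGFR signal, growth
  arrest when both P53 and EGFR are active).
* ``minifate_hypoxia`` — minifate plus a hypoxia-sensing receptor that
  drives an EGF-producing output node, closing the autocrine/paracrine
  loop through the environment.

Scenario configs carry the published experiment parameters (initial cells,
repeats, steps, decision window, substance constants) in their defaults and
record the legend strings in ``metadata`` for traceability.
"""

from __future__ import annotations

from pathlib import Path

from .config import MutationEvent, SimulationConfig, oxygen_substance
from .errors import BoolcellError, NetworkValidationError
from .microenv import NECROSIS_THRESHOLD_MM, SubstanceSpec
from .network import (
    Constraint,
    Edge,
    EdgeSign,
    FateAction,
    MutationProfile,
    NetworkModel,
    NodeKind,
    NodeSpec,
)
from .rules import BooleanRule

_ACT = EdgeSign.ACTIVATION
_INH = EdgeSign.INHIBITION

TOY_NETWORKS = ("toggle", "cascade", "minifate", "minifate_hypoxia")
SCENARIOS = (
    "starvation_growth",
    "mutation_order",
    "competition",
    "hypoxia",
    "control",
    "hypoxia_signaling",
)

# the published 53-node MAPK logical model is imported from file, never
# bundled; warn when a supplied file does not look like it
MAPK_EXPECTED_NODES = 53


def _gene(node_id: str, rule: str) -> NodeSpec:
    return NodeSpec(
        id=node_id, kind=NodeKind.GENE, rule=BooleanRule.from_expression(rule)
    )


def _fate(node_id: str, action: FateAction, rule: str) -> NodeSpec:
    return NodeSpec(
        id=node_id,
        kind=NodeKind.FATE,
        fate_action=action,
        rule=BooleanRule.from_expression(rule),
    )


def make_toy_network(name: str) -> NetworkModel:
    """Build one of the named toy networks."""
    if name == "toggle":
        return NetworkModel(
            name="toggle",
            nodes=[_gene("A", "!B"), _gene("B", "!A")],
            edges=[Edge("B", "A", _INH), Edge("A", "B", _INH)],
        )
    if name == "cascade":
        return NetworkModel(
            name="cascade",
            nodes=[
                _gene("G1", "G1"),
                _gene("G2", "G1"),
                _gene("G3", "G2"),
                _gene("G4", "G3"),
                _fate("Proliferation", FateAction.PROLIFERATION, "G4"),
            ],
            edges=[
                Edge("G1", "G2", _ACT),
                Edge("G2", "G3", _ACT),
                Edge("G3", "G4", _ACT),
                Edge("G4", "Proliferation", _ACT),
            ],
        )
    if name == "minifate":
        return NetworkModel(name="minifate", nodes=_minifate_nodes(), edges=_minifate_edges())
    if name == "minifate_hypoxia":
        nodes = _minifate_nodes() + [
            NodeSpec(id="HypoxiaSensor", kind=NodeKind.RECEPTOR),
            NodeSpec(
                id="EGF_out",
                kind=NodeKind.OUTPUT,
                rule=BooleanRule.from_expression("HypoxiaSensor"),
            ),
        ]
        edges = _minifate_edges() + [Edge("HypoxiaSensor", "EGF_out", _ACT)]
        return NetworkModel(name="minifate_hypoxia", nodes=nodes, edges=edges)
    raise BoolcellError(
        f"unknown toy network {name!r}; available: {', '.join(TOY_NETWORKS)}"
    )


def _minifate_nodes() -> list[NodeSpec]:
    return [
        NodeSpec(id="EGF", kind=NodeKind.RECEPTOR),
        _gene("EGFR", "EGF"),
        _gene("PTEN", "PTEN"),
        _gene("AKT", "EGFR & !PTEN"),
        _gene("P53", "!AKT"),
        _fate("Proliferation", FateAction.PROLIFERATION, "AKT & !P53"),
        _fate("Apoptosis", FateAction.APOPTOSIS, "P53 & !EGFR"),
        _fate("GrowthArrest", FateAction.GROWTH_ARREST, "P53 & EGFR"),
    ]


def _minifate_edges() -> list[Edge]:
    return [
        Edge("EGF", "EGFR", _ACT),
        Edge("EGFR", "AKT", _ACT),
        Edge("PTEN", "AKT", _INH),
        Edge("AKT", "P53", _INH),
        Edge("AKT", "Proliferation", _ACT),
        Edge("P53", "Proliferation", _INH),
        Edge("P53", "Apoptosis", _ACT),
        Edge("EGFR", "Apoptosis", _INH),
        Edge("P53", "GrowthArrest", _ACT),
        Edge("EGFR", "GrowthArrest", _ACT),
    ]


# ---------------------------------------------------------------------------
# clone panels


def minifate_clone_panel(equal_fractions: bool = True) -> list[MutationProfile]:
    """The eight clones from all combinations of EGFR+ (activating), p53-
    and PTEN- (loss-of-function) mutations, wild type included."""
    combos = [
        ("WT", {}),
        ("EGFR+", {"EGFR": 1}),
        ("p53-", {"P53": 0}),
        ("PTEN-", {"PTEN": 0}),
        ("EGFR+p53-", {"EGFR": 1, "P53": 0}),
        ("EGFR+PTEN-", {"EGFR": 1, "PTEN": 0}),
        ("p53-PTEN-", {"P53": 0, "PTEN": 0}),
        ("EGFR+p53-PTEN-", {"EGFR": 1, "P53": 0, "PTEN": 0}),
    ]
    frac = 1.0 / len(combos) if equal_fractions else 0.0
    return [
        MutationProfile(
            clone_label=label,
            constraints={g: Constraint(locked_value=v) for g, v in locks.items()},
            initial_fraction=frac,
        )
        for label, locks in combos
    ]


def clone_profile(label: str) -> MutationProfile:
    for p in minifate_clone_panel():
        if p.clone_label == label:
            return MutationProfile(
                clone_label=label,
                constraints=dict(p.constraints),
                initial_fraction=1.0,
            )
    raise BoolcellError(f"unknown clone label {label!r}")


# ---------------------------------------------------------------------------
# scenarios


def make_scenario(name: str, **overrides) -> SimulationConfig:
    """Ready-to-run configuration for a named study scenario.

    Defaults carry the published experiment parameters; ``overrides`` lets
    callers scale down replicates/steps for desk-size runs.
    """
    if name == "starvation_growth":
        cfg = SimulationConfig(
            network=make_toy_network("minifate"),
            profiles=minifate_clone_panel(),
            replicates=100,
            max_steps=2000,
            initial_cells=100,
            decision_window=100,
            lattice_dims=(41, 41, 41),
            isolation=True,
            metadata={
                "legend": "initial population: 100 cells; repeats: 100; "
                "length of simulation: 2,000 steps",
                "condition": "starvation (no growth factors, no diffusibles)",
            },
        )
    elif name == "competition":
        cfg = SimulationConfig(
            network=make_toy_network("minifate"),
            profiles=minifate_clone_panel(),
            replicates=100,
            max_steps=2000,
            initial_cells=100,
            decision_window=100,
            lattice_dims=(41, 41, 41),
            isolation=False,
            metadata={
                "legend": "the initial population was shared in equal parts "
                "among the eight clones",
            },
        )
    elif name == "mutation_order":
        panel = {p.clone_label: p for p in minifate_clone_panel(False)}
        clone1 = panel["EGFR+"]
        clone2 = panel["EGFR+p53-"]
        clone3 = panel["EGFR+p53-PTEN-"]
        clone1.initial_fraction = 1.0
        cfg = SimulationConfig(
            network=make_toy_network("minifate"),
            profiles=[clone1, clone2, clone3],
            replicates=100,
            max_steps=4000,
            initial_cells=50,
            decision_window=100,
            lattice_dims=(41, 41, 41),
            mutation_events=[
                MutationEvent(step=750, source_clone="EGFR+",
                              target_clone="EGFR+p53-", count=1),
                MutationEvent(step=1500, source_clone="EGFR+p53-",
                              target_clone="EGFR+p53-PTEN-", count=1),
            ],
            metadata={
                "legend": "At time point t = 750, we introduce a mutation to "
                "one cell, and at time point t = 1,500 an additional "
                "mutation",
            },
        )
    elif name in ("hypoxia", "control"):
        oxygen_level = 0.28 if name == "control" else 0.04
        cfg = SimulationConfig(
            network=make_toy_network("minifate"),
            profiles=minifate_clone_panel(),
            replicates=100,
            max_steps=2000,
            initial_cells=100,
            decision_window=100,
            lattice_dims=(45, 45, 45),
            sparsity=3,
            isolation=True,
            substances=[oxygen_substance(initial=oxygen_level, boundary=oxygen_level)],
            necrosis_threshold=NECROSIS_THRESHOLD_MM,
            metadata={
                "legend": f"initial and boundary condition: {oxygen_level} mM O2; "
                "R_O2 = 5.0e-3 mM/s, D_O2 = 1.0e-9 m^2/s; necrosis "
                "threshold 0.02 mM",
                "condition": name,
            },
        )
    elif name == "hypoxia_signaling":
        # EGF handled in production units: P0 = 1 unit/s, consumption and
        # activation threshold both 5.0e-4 of the production rate
        egf = SubstanceSpec(
            name="EGF",
            D_u=1.0e-9,
            R_0=5.0e-4,
            P_0=1.0,
            activation_threshold=5.0e-4,
            threshold_mode="active_above",
            receptor_node="EGF",
            output_node="EGF_out",
            initial_concentration=0.0,
            boundary_concentration=0.0,
        )
        # the sensor must fire above the 0.02 mM necrosis trigger to leave
        # the cell time to respond; 0.03 mM sits between the trigger and
        # the 0.04 mM ambient level
        hypoxia_receptor = oxygen_substance(
            initial=0.04,
            boundary=0.04,
            receptor_node="HypoxiaSensor",
            receptor_threshold=0.03,
        )
        panel = [
            clone_profile(label)
            for label in ("WT", "p53-", "PTEN-", "p53-PTEN-")
        ]
        for p in panel:
            p.initial_fraction = 0.25
        cfg = SimulationConfig(
            network=make_toy_network("minifate_hypoxia"),
            profiles=panel,
            replicates=100,
            max_steps=2000,
            initial_cells=500,
            decision_window=100,
            lattice_dims=(45, 45, 45),
            sparsity=3,
            substances=[hypoxia_receptor, egf],
            metadata={
                "legend": "0.04 mM O2, ACT_EGF = 5.0e-4, R_EGF = 5.0e-4 of "
                "the EGF production rate; initial population: 500 cells",
            },
        )
    else:
        raise BoolcellError(
            f"unknown scenario {name!r}; available: {', '.join(SCENARIOS)}"
        )
    for key, value in overrides.items():
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def mutation_schedule(
    config: SimulationConfig, events: list[MutationEvent]
) -> SimulationConfig:
    """Extend a configuration with timed clone-conversion events."""
    clones = {p.clone_label for p in config.profiles}
    for ev in events:
        for label in (ev.source_clone, ev.target_clone):
            if label not in clones:
                raise NetworkValidationError(
                    f"mutation event references unknown clone {label!r}"
                )
    return config.copy(mutation_events=list(config.mutation_events) + list(events))


# ---------------------------------------------------------------------------
# external network import


def import_mapk_network(path: str | Path) -> NetworkModel:
    """Import the published 53-node MAPK logical network from a GINML file.

    The model is distributed by its authors and is not bundled here; a
    node-count mismatch produces a warning, not an error, so derivative
    networks still load.
    """
    import logging

    from .io import parse_network

    net = parse_network(path)
    if len(net.nodes) != MAPK_EXPECTED_NODES:
        logging.getLogger(__name__).warning(
            "network %s has %d nodes; the published MAPK model has %d",
            path,
            len(net.nodes),
            MAPK_EXPECTED_NODES,
        )
    return net


def write_fixture(name: str, out_dir: str | Path) -> Path:
    """Write a named toy network (canonical text + GraphML) to a directory."""
    from .io import write_canonical, write_graphml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = make_toy_network(name)
    canonical = out / f"{name}.txt"
    write_canonical(net, canonical)
    write_graphml(net, out / f"{name}.graphml")
    return canonical
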