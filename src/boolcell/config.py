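"""Simulation configuration.

Keys mirror the original interface sliders ("Number of replicates", "Maximum
number of simulation steps", "Initial number of cells", "Cell decision
window", "Network update rate", "3D simulation") — accepted as aliases in
YAML files for traceability, alongside the snake_case field names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .microenv import NECROSIS_THRESHOLD_MM, OxygenParams, SubstanceSpec
from .network import MutationProfile, NetworkModel, validate_profiles

_ALIASES = {
    "Number of replicates": "replicates",
    "Maximum number of simulation steps": "max_steps",
    "Initial number of cells": "initial_cells",
    "Cell decision window": "decision_window",
    "Network update rate": "network_update_rate",
    "3D simulation": "three_d",
}


@dataclass
class MutationEvent:
    """At ``step``, relabel ``count`` random cells of ``source_clone`` to
    ``target_clone`` and apply the target's constraints to their live
    network states."""

    step: int
    source_clone: str
    target_clone: str
    count: int = 1


@dataclass
class SimulationConfig:
    network: NetworkModel | None = None
    network_path: str | None = None
    profiles: list[MutationProfile] = field(default_factory=list)
    substances: list[SubstanceSpec] = field(default_factory=list)

    replicates: int = 1
    max_steps: int = 1000
    initial_cells: int = 100
    decision_window: int = 100
    network_update_rate: int = 1
    dims: int = 3
    lattice_dims: tuple[int, int, int] = (41, 41, 41)
    sparsity: int = 1
    seed: int = 0

    slot_edge_m: float = 2.0e-5  # about one cell diameter
    seconds_per_step: float = 1.0
    max_diffusion_substeps: int = 200
    neighborhood: str = "moore"  # or "von_neumann"
    daughter_state: str = "copy"  # or "randomize"
    arrest_rounds: int = 3  # decision windows spent in growth arrest
    necrosis_threshold: float = NECROSIS_THRESHOLD_MM

    mutation_events: list[MutationEvent] = field(default_factory=list)
    isolation: bool = False  # run each clone as a separate monoclonal panel
    record_fields: bool = True
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dims == 2 and self.lattice_dims[2] != 1:
            self.lattice_dims = (self.lattice_dims[0], self.lattice_dims[1], 1)

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.network is None:
            raise ConfigError("no network specified")
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.max_steps < 1:
            raise ConfigError("max_steps must be >= 1")
        if self.initial_cells < 0:
            raise ConfigError("initial_cells must be >= 0")
        if self.decision_window < 1 or self.decision_window > self.max_steps:
            raise ConfigError("require 1 <= decision_window <= max_steps")
        if self.network_update_rate < 1:
            raise ConfigError("network_update_rate must be >= 1")
        if self.dims not in (2, 3):
            raise ConfigError("dims must be 2 or 3")
        if self.sparsity not in (1, 3):
            raise ConfigError("sparsity must be 1 or 3")
        if self.neighborhood not in ("moore", "von_neumann"):
            raise ConfigError(f"unknown neighborhood {self.neighborhood!r}")
        if self.daughter_state not in ("copy", "randomize"):
            raise ConfigError(f"unknown daughter_state {self.daughter_state!r}")
        capacity = (
            self.lattice_dims[0] * self.lattice_dims[1] * self.lattice_dims[2]
        )
        if self.initial_cells > capacity:
            raise ConfigError(
                f"{self.initial_cells} initial cells exceed lattice capacity "
                f"{capacity}"
            )
        validate_profiles(self.network, self.profiles)
        node_ids = set(self.network.node_ids)
        for s in self.substances:
            for attr in ("receptor_node", "output_node"):
                ref = getattr(s, attr)
                if ref is not None and ref not in node_ids:
                    raise ConfigError(
                        f"substance {s.name!r} references unknown node {ref!r}"
                    )

    # -- serialization ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        from .io import write_canonical, write_mutation_profiles

        path = Path(path)
        doc: dict = {}
        for f in dataclasses.fields(self):
            if f.name in ("network", "profiles", "substances", "mutation_events"):
                continue
            doc[f.name] = getattr(self, f.name)
        doc["lattice_dims"] = list(self.lattice_dims)
        if self.network_path:
            doc["network_path"] = self.network_path
        elif self.network is not None:
            net_path = path.with_suffix(".network.txt")
            write_canonical(self.network, net_path)
            doc["network_path"] = net_path.name
        if self.profiles:
            prof_path = path.with_suffix(".profiles.csv")
            write_mutation_profiles(self.profiles, prof_path)
            doc["profiles_path"] = prof_path.name
        doc["substances"] = [
            {
                k: v
                for k, v in dataclasses.asdict(s).items()
                if k != "oxygen" and v not in (None,)
            }
            for s in self.substances
        ]
        doc["mutation_events"] = [dataclasses.asdict(e) for e in self.mutation_events]
        path.write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        from .io import parse_network, read_canonical, read_mutation_profiles

        path = Path(path)
        doc = yaml.safe_load(path.read_text())
        if not isinstance(doc, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        for alias, name in _ALIASES.items():
            if alias in doc:
                doc[name] = doc.pop(alias)
        if doc.pop("three_d", None) is False:
            doc["dims"] = 2
        kwargs: dict = {}
        field_names = {f.name for f in dataclasses.fields(cls)}
        net_path = doc.pop("network_path", None)
        prof_path = doc.pop("profiles_path", None)
        substances = doc.pop("substances", [])
        events = doc.pop("mutation_events", [])
        for key, value in doc.items():
            if key not in field_names:
                raise ConfigError(f"{path}: unknown config key {key!r}")
            kwargs[key] = value
        if "lattice_dims" in kwargs:
            kwargs["lattice_dims"] = tuple(kwargs["lattice_dims"])
        cfg = cls(**kwargs)
        if net_path:
            full = (path.parent / net_path).resolve()
            if not full.exists():
                raise ConfigError(f"{path}: network file {full} not found")
            cfg.network_path = str(full)
            if full.suffix in (".txt", ".bnet"):
                cfg.network = read_canonical(full)
            else:
                cfg.network = parse_network(full)
        if prof_path:
            full = (path.parent / prof_path).resolve()
            if not full.exists():
                raise ConfigError(f"{path}: profile file {full} not found")
            cfg.profiles = read_mutation_profiles(full)
        cfg.substances = [
            s if isinstance(s, SubstanceSpec) else SubstanceSpec(**s)
            for s in substances
        ]
        cfg.mutation_events = [
            e if isinstance(e, MutationEvent) else MutationEvent(**e)
            for e in events
        ]
        return cfg

    def copy(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)


def oxygen_substance(
    initial: float,
    boundary: float,
    D: float = 1.0e-9,
    R_0: float = 5.0e-3,
    receptor_node: str | None = None,
    activation_threshold: float = NECROSIS_THRESHOLD_MM,
    receptor_threshold: float | None = None,
) -> SubstanceSpec:
    """Oxygen with the standard consumption law (C_opt = 0.28 mM, floor at
    80% of the activation threshold, which doubles as the necrosis trigger).

    ``receptor_threshold`` sets the hypoxia-sensing step function separately
    from the consumption/necrosis threshold: a sensor firing only at the
    necrosis trigger would never act before the cell dies.
    """
    return SubstanceSpec(
        name="oxygen",
        D_u=D,
        R_0=R_0,
        activation_threshold=(
            receptor_threshold if receptor_threshold is not None
            else activation_threshold
        ),
        threshold_mode="active_below",
        receptor_node=receptor_node,
        initial_concentration=initial,
        boundary_concentration=boundary,
        is_oxygen=True,
        oxygen=OxygenParams(activation_threshold=activation_threshold),
    )
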