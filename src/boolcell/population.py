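"""Cell agents on the slot lattice and the per-tick world update.

Each cell occupies one lattice slot and carries its own copy of the network
state.  A global tick performs, in order: receptor synchronisation (and the
low-oxygen necrosis precondition), one or more asynchronous network updates
per living non-arrested cell, immediate fate execution (apoptosis removes the
cell, necrosis freezes it in place), deferred fate execution at decision-window
boundaries (proliferation into a random free neighbor slot, growth arrest for
blocked or network-decided cells), and finally one diffusion advance of every
substance field using the current sinks and sources.

Network updates are vectorized across cells of the same clone; this is exact
because cells only interact through the shared concentration fields, which are
synchronised once per tick.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .config import SimulationConfig
from .engine import CompiledNetwork
from .errors import CapacityError, ConfigError
from .microenv import (
    ConcentrationField,
    SubstanceSpec,
    advance,
    necrosis_precondition,
    oxygen_sink_rate,
)
from .network import (
    FateAction,
    MutationProfile,
    NetworkModel,
    apply_mutation_profile,
)


class CellStatus(enum.IntEnum):
    ALIVE = 0
    ARRESTED = 1
    NECROTIC = 2
    REMOVED = 3  # apoptosed; slot freed, row retired


CONSUMPTION_MULTIPLIER = {
    CellStatus.ALIVE: 1.0,
    CellStatus.ARRESTED: 0.5,
    CellStatus.NECROTIC: 0.0,
    CellStatus.REMOVED: 0.0,
}


@dataclass(frozen=True)
class Cell:
    """Read-only view of one cell agent."""

    id: int
    position: tuple[int, int, int]
    clone_label: str
    status: CellStatus
    arrest_rounds_remaining: int
    net_state: dict[str, int]

    @property
    def consumption_multiplier(self) -> float:
        return CONSUMPTION_MULTIPLIER[self.status]


def neighbor_offsets(dims: int, neighborhood: str) -> np.ndarray:
    """Moore (8 in 2D, 26 in 3D) or von Neumann (4/6) displacement vectors."""
    if neighborhood == "moore":
        rng_k = (0,) if dims == 2 else (-1, 0, 1)
        offs = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in rng_k
            if (i, j, k) != (0, 0, 0)
        ]
    elif neighborhood == "von_neumann":
        offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)]
        if dims == 3:
            offs += [(0, 0, 1), (0, 0, -1)]
    else:
        raise ConfigError(f"unknown neighborhood {neighborhood!r}")
    return np.array(offs, dtype=np.int64)


class SlotLattice:
    """Rectangular slot grid; at most one cell per slot."""

    def __init__(self, dims: tuple[int, int, int]):
        self.dims = tuple(int(d) for d in dims)
        self.occupancy = np.full(self.dims, -1, dtype=np.int64)

    @property
    def capacity(self) -> int:
        return int(np.prod(self.dims))

    def in_bounds(self, pos) -> bool:
        return all(0 <= pos[a] < self.dims[a] for a in range(3))

    def is_free(self, pos) -> bool:
        return self.occupancy[tuple(pos)] == -1

    def place(self, cell_id: int, pos) -> None:
        pos = tuple(int(x) for x in pos)
        if self.occupancy[pos] != -1:
            raise CapacityError(f"slot {pos} already occupied")
        self.occupancy[pos] = cell_id

    def free(self, pos) -> None:
        self.occupancy[tuple(pos)] = -1

    def free_neighbors(self, pos, offsets: np.ndarray) -> list[tuple[int, int, int]]:
        out = []
        for off in offsets:
            q = (int(pos[0] + off[0]), int(pos[1] + off[1]), int(pos[2] + off[2]))
            if self.in_bounds(q) and self.occupancy[q] == -1:
                out.append(q)
        return out

    def center(self) -> tuple[float, float, float]:
        return tuple((d - 1) / 2.0 for d in self.dims)


def clone_counts(fractions: Iterable[float], n: int) -> list[int]:
    """Largest-remainder apportionment of n cells over clone fractions."""
    fr = np.asarray(list(fractions), dtype=float)
    exact = fr * n
    base = np.floor(exact).astype(int)
    short = n - int(base.sum())
    if short > 0:
        order = np.argsort(-(exact - base), kind="stable")
        for i in order[:short]:
            base[i] += 1
    return base.tolist()


def placement_order(
    lattice: SlotLattice, rng: np.random.Generator
) -> np.ndarray:
    """All slots ordered by Euclidean distance from the lattice center, ties
    broken uniformly at random.  Returns an (N, 3) array of positions."""
    grids = np.indices(lattice.dims).reshape(3, -1).T
    center = np.array(lattice.center())
    d2 = ((grids - center) ** 2).sum(axis=1)
    tie = rng.random(len(grids))
    order = np.lexsort((tie, d2))
    return grids[order]


class World:
    """The full simulation state for one replicate."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        self.rng = rng
        self.network: NetworkModel = config.network
        self.lattice = SlotLattice(config.lattice_dims)
        self.offsets = neighbor_offsets(config.dims, config.neighborhood)
        self.step = 0

        # clone table: append implicit wild type if fractions leave room
        profiles = list(config.profiles)
        if not profiles:
            profiles = [MutationProfile(clone_label="WT", initial_fraction=1.0)]
        total = sum(p.initial_fraction for p in profiles)
        if total < 1.0 - 1e-9 and not any(p.clone_label == "WT" for p in profiles):
            profiles.append(
                MutationProfile(clone_label="WT", initial_fraction=1.0 - total)
            )
        self.profiles = profiles
        self.clone_labels = [p.clone_label for p in profiles]
        self.compiled: list[CompiledNetwork] = [
            CompiledNetwork(apply_mutation_profile(self.network, p))
            for p in profiles
        ]
        self.n_nodes = self.compiled[0].n
        self.node_index = self.compiled[0].index

        # substance fields
        self.fields: dict[str, ConcentrationField] = {}
        for s in config.substances:
            self.fields[s.name] = ConcentrationField.for_lattice(
                config.lattice_dims,
                config.slot_edge_m,
                config.sparsity,
                s.initial_concentration,
                s.boundary_concentration,
            )

        # cell arrays (rows are cell ids; grown on demand, never reused)
        cap = max(16, config.initial_cells * 2)
        self._cap = cap
        self.S = np.zeros((cap, self.n_nodes), dtype=np.uint8)
        self.status = np.full(cap, -1, dtype=np.int8)  # -1 = unused row
        self.clone = np.zeros(cap, dtype=np.int32)
        self.pos = np.zeros((cap, 3), dtype=np.int64)
        self.arrest_rounds = np.zeros(cap, dtype=np.int32)
        self.arrest_entered = np.full(cap, -(10**9), dtype=np.int64)
        self.n_rows = 0

        self.events: list[tuple] = []
        self.counts_log: list[tuple] = []
        self.center_log: list[tuple] = []
        self._decisions_pending: dict[int, FateAction] = {}

        if config.initial_cells > 0:
            self._seed_population(config.initial_cells)
        self._record_counts()

    # -- bookkeeping -----------------------------------------------------
    def _grow(self, need: int) -> None:
        while self._cap < need:
            self._cap *= 2
        for name in ("S", "status", "clone", "pos", "arrest_rounds", "arrest_entered"):
            arr = getattr(self, name)
            if arr.shape[0] < self._cap:
                pad_shape = (self._cap - arr.shape[0],) + arr.shape[1:]
                fill = -1 if name == "status" else (-(10**9) if name == "arrest_entered" else 0)
                setattr(
                    self,
                    name,
                    np.concatenate([arr, np.full(pad_shape, fill, dtype=arr.dtype)]),
                )

    def _new_row(self) -> int:
        self._grow(self.n_rows + 1)
        row = self.n_rows
        self.n_rows += 1
        return row

    def _log(self, event: str, row: int) -> None:
        p = self.pos[row]
        self.events.append(
            (
                self.step,
                int(row),
                self.clone_labels[self.clone[row]],
                event,
                int(p[0]),
                int(p[1]),
                int(p[2]),
            )
        )

    def rows_with_status(self, *statuses: CellStatus) -> np.ndarray:
        mask = np.isin(self.status[: self.n_rows], [int(s) for s in statuses])
        return np.flatnonzero(mask)

    @property
    def living_rows(self) -> np.ndarray:
        return self.rows_with_status(CellStatus.ALIVE, CellStatus.ARRESTED)

    @property
    def n_living(self) -> int:
        return len(self.living_rows)

    def cell(self, cell_id: int) -> Cell:
        if self.status[cell_id] < 0:
            raise KeyError(f"no cell with id {cell_id}")
        cn = self.compiled[self.clone[cell_id]]
        return Cell(
            id=int(cell_id),
            position=tuple(int(x) for x in self.pos[cell_id]),
            clone_label=self.clone_labels[self.clone[cell_id]],
            status=CellStatus(int(self.status[cell_id])),
            arrest_rounds_remaining=int(self.arrest_rounds[cell_id]),
            net_state=cn.array_to_state(self.S[cell_id]),
        )

    # -- seeding ---------------------------------------------------------
    def _seed_population(self, n: int) -> None:
        if n > self.lattice.capacity:
            raise CapacityError(
                f"{n} cells exceed lattice capacity {self.lattice.capacity}"
            )
        slots = placement_order(self.lattice, self.rng)[:n]
        counts = clone_counts(
            [p.initial_fraction for p in self.profiles], n
        )
        labels = np.repeat(np.arange(len(self.profiles)), counts)
        self.rng.shuffle(labels)
        for pos, clone_idx in zip(slots, labels):
            row = self._new_row()
            cn = self.compiled[clone_idx]
            self.S[row] = cn.random_states(1, self.rng)[0]
            self.status[row] = CellStatus.ALIVE
            self.clone[row] = clone_idx
            self.pos[row] = pos
            self.lattice.place(row, pos)
            self._log("seed", row)

    # -- fate actions ----------------------------------------------------
    def act_apoptosis(self, row: int) -> None:
        """The cell dies and is removed; its slot becomes reusable."""
        self._log("apoptosis", row)
        self.lattice.free(self.pos[row])
        self.status[row] = CellStatus.REMOVED

    def act_necrosis(self, row: int) -> None:
        """The cell dies in place: it keeps its slot forever but no longer
        consumes, updates or acts."""
        self._log("necrosis", row)
        self.status[row] = CellStatus.NECROTIC
        self.arrest_rounds[row] = 0

    def act_growth_arrest(self, row: int) -> None:
        """Pause the cell's network for ``arrest_rounds`` decision windows;
        consumption drops to half while paused."""
        self._log("arrest", row)
        self.status[row] = CellStatus.ARRESTED
        self.arrest_rounds[row] = self.config.arrest_rounds
        self.arrest_entered[row] = self.step

    def act_proliferate(self, row: int) -> int | None:
        """Place a daughter in a uniformly random free neighbor slot; if the
        neighborhood is full the parent enters growth arrest instead.

        The daughter inherits the clone and (by default) a copy of the
        parent's current network state; the proliferation fate node is reset
        in both so each must re-decide in a later window.  Returns the
        daughter row id, or None when blocked.
        """
        free = self.lattice.free_neighbors(self.pos[row], self.offsets)
        if not free:
            self.act_growth_arrest(row)
            return None
        target = free[self.rng.integers(len(free))]
        clone_idx = self.clone[row]
        cn = self.compiled[clone_idx]
        daughter = self._new_row()
        if self.config.daughter_state == "randomize":
            self.S[daughter] = cn.random_states(1, self.rng)[0]
        else:
            self.S[daughter] = self.S[row]
        pro_idx = cn.fate_idx[FateAction.PROLIFERATION]
        self.S[row, pro_idx] = 0
        self.S[daughter, pro_idx] = 0
        self.status[daughter] = CellStatus.ALIVE
        self.clone[daughter] = clone_idx
        self.pos[daughter] = target
        self.lattice.place(daughter, target)
        self._log("divide", row)
        self._log("birth", daughter)
        return daughter

    # -- tick phases -----------------------------------------------------
    def _sync_receptors(self) -> None:
        living = self.living_rows
        if len(living) == 0:
            return
        s = self.config.sparsity
        vox = self.pos[living] // s
        for spec in self.config.substances:
            field = self.fields[spec.name]
            conc = field.grid[vox[:, 0], vox[:, 1], vox[:, 2]]
            if spec.receptor_node is not None:
                j = self.node_index[spec.receptor_node]
                if spec.threshold_mode == "active_above":
                    bits = (conc >= spec.activation_threshold).astype(np.uint8)
                else:
                    bits = (conc < spec.activation_threshold).astype(np.uint8)
                self.S[living, j] = bits
            if spec.is_oxygen:
                starved = conc < self.config.necrosis_threshold
                for row in living[starved]:
                    self.act_necrosis(int(row))

    def _network_phase(self) -> None:
        for _ in range(self.config.network_update_rate):
            active = self.rows_with_status(CellStatus.ALIVE)
            if len(active) == 0:
                return
            for clone_idx, cn in enumerate(self.compiled):
                rows = active[self.clone[active] == clone_idx]
                if len(rows) == 0:
                    continue
                S = self.S[rows]
                N = cn.next_values(S)
                apo, nec = cn.immediate_fate(S, N)
                cn.async_flip(S, N, self.rng, rows=~(apo | nec))
                self.S[rows] = S
                for r in rows[apo]:
                    self.act_apoptosis(int(r))
                for r in rows[nec]:
                    self.act_necrosis(int(r))

    def _window_phase(self) -> None:
        # deferred fates, evaluated in a fresh random order
        candidates = self.rows_with_status(CellStatus.ALIVE)
        if len(candidates) > 0:
            order = self.rng.permutation(len(candidates))
            for i in order:
                row = int(candidates[i])
                if self.status[row] != CellStatus.ALIVE:
                    continue  # may have arrested earlier in this window
                cn = self.compiled[self.clone[row]]
                S = self.S[row][None, :]
                pro, ga = cn.deferred_fate(S)
                if pro[0]:
                    self.act_proliferate(row)
                elif ga[0]:
                    self.act_growth_arrest(row)
        # arrest counters tick down once per window; cells entering arrest
        # this window keep the full count (decrement starts next window)
        arrested = self.rows_with_status(CellStatus.ARRESTED)
        lo = self.step - self.config.decision_window
        for row in arrested:
            row = int(row)
            if self.arrest_entered[row] > lo:
                continue  # entered arrest during this window; full count ahead
            self.arrest_rounds[row] -= 1
            if self.arrest_rounds[row] <= 0:
                self.status[row] = CellStatus.ALIVE
                self.arrest_rounds[row] = 0
                self._log("arrest_release", row)

    def _mutation_events_phase(self) -> None:
        for ev in self.config.mutation_events:
            if ev.step != self.step:
                continue
            try:
                src = self.clone_labels.index(ev.source_clone)
                dst = self.clone_labels.index(ev.target_clone)
            except ValueError as exc:
                raise ConfigError(
                    f"mutation event references unknown clone: {exc}"
                ) from exc
            living = self.living_rows
            pool = living[self.clone[living] == src]
            if len(pool) == 0:
                import logging

                logging.getLogger(__name__).warning(
                    "mutation event at step %d skipped: no %s cells alive",
                    ev.step,
                    ev.source_clone,
                )
                continue
            take = min(ev.count, len(pool))
            chosen = self.rng.choice(pool, size=take, replace=False)
            cn = self.compiled[dst]
            for row in chosen:
                row = int(row)
                self.clone[row] = dst
                state = self.S[row][None, :].copy()
                cn.apply_pins(state)
                self.S[row] = state[0]
                self._log("mutation", row)

    def _environment_phase(self) -> None:
        if not self.fields:
            return
        s = self.config.sparsity
        dt = self.config.seconds_per_step
        rows = self.rows_with_status(CellStatus.ALIVE, CellStatus.ARRESTED)
        vox = self.pos[rows] // s if len(rows) else np.zeros((0, 3), dtype=np.int64)
        mult = np.where(
            self.status[rows] == CellStatus.ARRESTED, 0.5, 1.0
        ) if len(rows) else np.zeros(0)
        for spec in self.config.substances:
            field = self.fields[spec.name]
            if spec.is_oxygen:
                msum = np.zeros(field.grid.shape)
                if len(rows):
                    np.add.at(msum, (vox[:, 0], vox[:, 1], vox[:, 2]), mult)
                oxy = spec.oxygen
                R0, CNf, Copt = spec.R_0, oxy.C_Nf, oxy.C_opt

                def sink(grid, _m=msum, _R0=R0, _CNf=CNf, _Copt=Copt):
                    return -_m * _R0 * np.maximum(grid - _CNf, 0.0) / (_Copt - _CNf)

                advance(
                    field,
                    spec.D_u,
                    dt,
                    sink,
                    max_substeps=self.config.max_diffusion_substeps,
                )
            else:
                src = np.zeros(field.grid.shape)
                if len(rows):
                    per_cell = np.zeros(len(rows))
                    if spec.output_node is not None:
                        j = self.node_index[spec.output_node]
                        per_cell += spec.P_0 * (self.S[rows, j] == 1)
                    if spec.receptor_node is not None:
                        j = self.node_index[spec.receptor_node]
                        per_cell -= spec.R_0 * (self.S[rows, j] == 1)
                    # arrested cells interact with the environment at half rate
                    per_cell *= mult
                    np.add.at(src, (vox[:, 0], vox[:, 1], vox[:, 2]), per_cell)
                advance(
                    field,
                    spec.D_u,
                    dt,
                    src,
                    max_substeps=self.config.max_diffusion_substeps,
                )
            if self.config.record_fields:
                self.center_log.append(
                    (self.step, spec.name, field.center_value())
                )

    def _record_counts(self) -> None:
        for clone_idx, label in enumerate(self.clone_labels):
            rows = np.flatnonzero(
                (self.status[: self.n_rows] >= 0)
                & (self.clone[: self.n_rows] == clone_idx)
            )
            st = self.status[rows]
            self.counts_log.append(
                (
                    self.step,
                    label,
                    int((st == CellStatus.ALIVE).sum()),
                    int((st == CellStatus.ARRESTED).sum()),
                    int((st == CellStatus.NECROTIC).sum()),
                )
            )

    def tick(self) -> None:
        """One global simulation step (see module docstring for the order)."""
        self.step += 1
        self._sync_receptors()
        self._network_phase()
        self._mutation_events_phase()
        if self.step % self.config.decision_window == 0:
            self._window_phase()
        self._environment_phase()
        self._record_counts()

    def run(self, max_steps: int | None = None) -> None:
        limit = self.config.max_steps if max_steps is None else max_steps
        while self.step < limit:
            if self.n_living == 0:
                break
            self.tick()

    # -- invariants ------------------------------------------------------
    def check_invariants(self) -> None:
        """Occupancy/population consistency; raises AssertionError."""
        occupied = np.flatnonzero(self.lattice.occupancy.ravel() != -1)
        present = self.rows_with_status(
            CellStatus.ALIVE, CellStatus.ARRESTED, CellStatus.NECROTIC
        )
        assert len(occupied) == len(present), "occupancy/cell count mismatch"
        for row in present:
            p = tuple(self.pos[row])
            assert self.lattice.occupancy[p] == row, (
                f"cell {row} position desynchronised"
            )
        arrested = self.rows_with_status(CellStatus.ARRESTED)
        assert (self.arrest_rounds[arrested] > 0).all(), (
            "arrested cell without remaining rounds"
        )
        alive = self.rows_with_status(CellStatus.ALIVE)
        assert (self.arrest_rounds[alive] == 0).all(), (
            "alive cell with arrest counter"
        )
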