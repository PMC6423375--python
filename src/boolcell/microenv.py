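"""Voxel-based diffusive microenvironment.

Each substance lives on a rectangular voxel grid and obeys the
diffusion–reaction equation  du/dt = D * laplacian(u) + S,  integrated with an
explicit forward-time central-space (FTCS) scheme under Dirichlet boundary
conditions.  Cells act as sources and sinks:

* oxygen is consumed at a rate proportional to the local concentration,
  S = R0 * (C - C_Nf) / (C_opt - C_Nf), floored at 0 below C_Nf; arrested
  cells consume at half rate and necrotic cells not at all;
* user-defined diffusibles are produced at P0 per cell with an active output
  node and consumed at R0 per cell with an active receptor node.

Concentrations couple back into the networks through step functions on
receptor nodes, and extreme oxygen deprivation (below the necrosis
threshold) forces the necrotic fate regardless of network state.

Grid "sparsity" sets how many cell slots a voxel covers (1x1x1 or 3x3x3);
the per-voxel source is the plain sum of its cells' source terms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .errors import ConfigError, StabilityError

logger = logging.getLogger(__name__)

NECROSIS_THRESHOLD_MM = 0.02  # mM O2, forces the necrotic fate below it


@dataclass(frozen=True)
class OxygenParams:
    """Oxygen consumption-law constants.

    The consumption floor ``C_Nf`` sits at 80% of the activation threshold,
    which is identified with the necrosis trigger concentration.
    """

    C_opt: float = 0.28  # mM, optimal oxygen concentration
    activation_threshold: float = NECROSIS_THRESHOLD_MM  # mM

    def __post_init__(self):
        if not (0 <= self.C_Nf < self.C_opt):
            raise ConfigError(
                f"oxygen params require 0 <= C_Nf ({self.C_Nf}) < C_opt "
                f"({self.C_opt})"
            )

    @property
    def C_Nf(self) -> float:
        return 0.8 * self.activation_threshold


@dataclass
class SubstanceSpec:
    """Definition of one diffusible substance.

    Rates are per cell: ``R_0`` consumption and ``P_0`` production
    (mM/s for oxygen; user units/s for other diffusibles).  ``receptor_node``
    and ``output_node`` name the network nodes coupled to this substance.
    """

    name: str
    D_u: float  # diffusion coefficient, m^2/s
    R_0: float = 0.0
    P_0: float = 0.0
    activation_threshold: float = 0.0
    threshold_mode: str = "active_above"  # or "active_below"
    receptor_node: str | None = None
    output_node: str | None = None
    initial_concentration: float = 0.0
    boundary_concentration: float = 0.0
    is_oxygen: bool = False
    oxygen: OxygenParams | None = None

    def __post_init__(self):
        if self.D_u < 0 or self.R_0 < 0 or self.P_0 < 0:
            raise ConfigError(f"substance {self.name!r}: negative coefficient")
        if self.threshold_mode not in ("active_above", "active_below"):
            raise ConfigError(
                f"substance {self.name!r}: unknown threshold_mode "
                f"{self.threshold_mode!r}"
            )
        if self.is_oxygen and self.oxygen is None:
            self.oxygen = OxygenParams()


@dataclass
class ConcentrationField:
    """Concentration grid for one substance with Dirichlet boundaries.

    ``grid`` is always a 3D array; 2D/1D problems use singleton trailing
    axes.  ``h`` is the voxel edge (m); ``sparsity`` the number of cell
    slots per voxel edge.
    """

    grid: np.ndarray
    h: float
    boundary_concentration: float
    sparsity: int = 1

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float64)
        while self.grid.ndim < 3:
            self.grid = self.grid[..., None]

    @classmethod
    def for_lattice(
        cls,
        lattice_dims: tuple[int, int, int],
        h_slot: float,
        sparsity: int,
        initial: float,
        boundary: float,
    ) -> "ConcentrationField":
        if sparsity not in (1, 3):
            raise ConfigError("grid sparsity must be 1 or 3")
        shape = tuple(math.ceil(d / sparsity) for d in lattice_dims)
        grid = np.full(shape, initial, dtype=np.float64)
        f = cls(
            grid=grid,
            h=h_slot * sparsity,
            boundary_concentration=boundary,
            sparsity=sparsity,
        )
        f.pin_boundary()
        return f

    @property
    def active_axes(self) -> list[int]:
        return [ax for ax in range(3) if self.grid.shape[ax] > 1]

    @property
    def dims(self) -> int:
        return max(1, len(self.active_axes))

    def pin_boundary(self) -> None:
        for ax in self.active_axes:
            sl0 = [slice(None)] * 3
            sl1 = [slice(None)] * 3
            sl0[ax], sl1[ax] = 0, -1
            self.grid[tuple(sl0)] = self.boundary_concentration
            self.grid[tuple(sl1)] = self.boundary_concentration

    def voxel_of_slot(self, pos) -> tuple[int, int, int]:
        s = self.sparsity
        return (pos[0] // s, pos[1] // s, pos[2] // s)

    def value_at_slot(self, pos) -> float:
        return float(self.grid[self.voxel_of_slot(pos)])

    def center_value(self) -> float:
        c = tuple(d // 2 for d in self.grid.shape)
        return float(self.grid[c])


def _laplacian(field: ConcentrationField) -> np.ndarray:
    u = field.grid
    lap = np.zeros_like(u)
    h2 = field.h * field.h
    for ax in field.active_axes:
        lap += (np.roll(u, 1, axis=ax) + np.roll(u, -1, axis=ax) - 2 * u) / h2
    return lap


def stable_dt(field: ConcentrationField, D: float) -> float:
    """Largest time step satisfying the FTCS bound alpha <= 1/(2*dims)."""
    if D == 0:
        return math.inf
    return field.h * field.h / (2 * field.dims * D)


def ftcs_step(
    field: ConcentrationField,
    D: float,
    dt: float,
    source_grid: np.ndarray | float = 0.0,
) -> ConcentrationField:
    """One explicit FTCS step, in place.

    Refuses if alpha = D*dt/h^2 exceeds 1/(2*dims); negative concentrations
    produced by strong sinks are clamped to zero with a logged warning; the
    boundary is re-pinned after the update (the roll-based Laplacian wraps
    only at boundary voxels, which the re-pin overwrites).
    """
    alpha_max = 1.0 / (2 * field.dims)
    alpha = D * dt / (field.h * field.h)
    if alpha > alpha_max * (1 + 1e-12):
        raise StabilityError(alpha, alpha_max, math.ceil(alpha / alpha_max))
    field.grid += dt * (D * _laplacian(field) + source_grid)
    neg = field.grid < 0
    if neg.any():
        logger.warning(
            "clamped %d negative concentration voxels to 0", int(neg.sum())
        )
        field.grid[neg] = 0.0
    field.pin_boundary()
    return field


def advance(
    field: ConcentrationField,
    D: float,
    duration: float,
    source_fn: Callable[[np.ndarray], np.ndarray] | np.ndarray | float = 0.0,
    max_substeps: int | None = None,
) -> float:
    """Advance the field by ``duration`` seconds, auto-subdividing into
    FTCS-stable substeps.

    ``source_fn`` may be a constant grid or a callable of the current grid
    (used for the concentration-dependent oxygen sink).  When the required
    substep count exceeds ``max_substeps`` the advance is truncated to
    ``max_substeps`` stable steps (quasi-steady-state tracking); returns the
    simulated time actually covered.
    """
    if D == 0 and not callable(source_fn):
        field.grid += duration * np.asarray(source_fn, dtype=np.float64)
        field.grid[field.grid < 0] = 0.0
        field.pin_boundary()
        return duration
    dt_max = stable_dt(field, D)
    n = max(1, math.ceil(duration / dt_max)) if math.isfinite(dt_max) else 1
    if max_substeps is not None and n > max_substeps:
        logger.debug(
            "diffusion advance truncated: %d substeps needed, capped at %d",
            n,
            max_substeps,
        )
        n = max_substeps
        dt = dt_max
    else:
        dt = duration / n
    for _ in range(n):
        src = source_fn(field.grid) if callable(source_fn) else source_fn
        ftcs_step(field, D, dt, src)
    return n * dt


def relax_to_steady_state(
    field: ConcentrationField,
    D: float,
    source_fn: Callable[[np.ndarray], np.ndarray] | np.ndarray | float = 0.0,
    tol: float = 1e-10,
    max_iter: int = 2_000_000,
) -> int:
    """Iterate FTCS at the stability limit until the per-step change falls
    below ``tol`` (max absolute change per step).  Returns iterations used."""
    dt = stable_dt(field, D)
    if not math.isfinite(dt):
        return 0
    it = 0
    while it < max_iter:
        prev = field.grid.copy()
        src = source_fn(field.grid) if callable(source_fn) else source_fn
        ftcs_step(field, D, dt, src)
        it += 1
        if np.max(np.abs(field.grid - prev)) < tol:
            break
    return it


# ---------------------------------------------------------------------------
# cell coupling primitives


def oxygen_sink_rate(
    C: float | np.ndarray,
    R_0: float,
    oxy: OxygenParams,
    multiplier: float = 1.0,
) -> float | np.ndarray:
    """Consumption magnitude S = m * R0 * (C - C_Nf)/(C_opt - C_Nf),
    floored at 0 below the C_Nf floor; enters the PDE as a negative source.

    Multiplier: 1.0 for living cells, 0.5 in growth arrest, 0.0 necrotic.
    """
    S = multiplier * R_0 * (np.asarray(C) - oxy.C_Nf) / (oxy.C_opt - oxy.C_Nf)
    S = np.maximum(S, 0.0)
    return float(S) if np.isscalar(C) else S


def substance_source_sink(
    receptor_active: int, output_active: int, R_0: float, P_0: float
) -> float:
    """Net per-cell source for a diffusible: production P0 when the output
    node is active minus consumption R0 when the receptor is active."""
    return P_0 * output_active - R_0 * receptor_active


def receptor_bit(concentration: float, threshold: float, mode: str) -> int:
    """Step-function coupling: active_above uses >= (threshold included),
    active_below uses strict <."""
    if mode == "active_above":
        return 1 if concentration >= threshold else 0
    if mode == "active_below":
        return 1 if concentration < threshold else 0
    raise ConfigError(f"unknown threshold mode {mode!r}")


def receptor_sync(
    position,
    fields: Mapping[str, ConcentrationField],
    substances: list[SubstanceSpec],
) -> dict[str, int]:
    """Receptor bits for a cell at a lattice position, one per substance
    with a linked receptor node."""
    bits: dict[str, int] = {}
    for s in substances:
        if s.receptor_node is None:
            continue
        c = fields[s.name].value_at_slot(position)
        bits[s.receptor_node] = receptor_bit(
            c, s.activation_threshold, s.threshold_mode
        )
    return bits


def necrosis_precondition(
    C_local: float, threshold: float = NECROSIS_THRESHOLD_MM
) -> bool:
    """True iff local oxygen is strictly below the necrosis threshold."""
    return C_local < threshold
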