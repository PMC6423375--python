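"""Spheroid- and population-level measures.

Sphericity follows psi = pi^(1/3) * (6V)^(2/3) / A with the volume counted in
slots (V = n * h^3) and the surface area counted in exposed voxel faces
(A = faces * h^2).  Absolute values are therefore discretization-dependent
(a digitized ball never reaches psi = 1); comparisons between spheroids on
the same lattice are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

_FACE_OFFSETS = [
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
]


@dataclass(frozen=True)
class ShapeSummary:
    volume: float  # m^3
    area: float  # m^2
    sphericity: float
    radius: float  # mean outermost distance, in slot units

    n_slots: int
    n_surface: int


def _as_set(occupied) -> set[tuple[int, int, int]]:
    out = {tuple(int(x) for x in p) for p in occupied}
    if not out:
        raise ValueError("occupied set must be non-empty")
    return out


def exposed_faces(occupied) -> int:
    """Count slot faces adjacent to an empty slot or the outside."""
    occ = _as_set(occupied)
    faces = 0
    for p in occ:
        for off in _FACE_OFFSETS:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q not in occ:
                faces += 1
    return faces


def surface_slots(occupied) -> list[tuple[int, int, int]]:
    """Occupied slots with at least one empty face neighbor."""
    occ = _as_set(occupied)
    out = []
    for p in occ:
        for off in _FACE_OFFSETS:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q not in occ:
                out.append(p)
                break
    return out


def sphericity(occupied, h: float = 1.0) -> float:
    """psi = pi^(1/3) (6V)^(2/3) / A over the voxelized occupied set."""
    occ = _as_set(occupied)
    V = len(occ) * h**3
    A = exposed_faces(occ) * h**2
    return math.pi ** (1 / 3) * (6 * V) ** (2 / 3) / A


def radius(occupied, center: Sequence[float]) -> float:
    """Mean Euclidean distance from the stored initial center to the
    outermost (surface) cells, in slot units."""
    surf = np.array(surface_slots(occupied), dtype=float)
    c = np.asarray(center, dtype=float)
    return float(np.linalg.norm(surf - c, axis=1).mean())


def shape_summary(occupied, center: Sequence[float], h: float = 1.0) -> ShapeSummary:
    occ = _as_set(occupied)
    faces = exposed_faces(occ)
    V = len(occ) * h**3
    A = faces * h**2
    return ShapeSummary(
        volume=V,
        area=A,
        sphericity=math.pi ** (1 / 3) * (6 * V) ** (2 / 3) / A,
        radius=radius(occ, center),
        n_slots=len(occ),
        n_surface=len(surface_slots(occ)),
    )


def doubling_time(
    living_counts: Mapping[int, float] | pd.Series,
    initial_count: float,
    decision_window: int,
) -> float | None:
    """First time the living count reaches twice the initial count, linearly
    interpolated between bracketing samples and expressed in decision rounds
    (steps / decision_window).  None if the count never doubles."""
    series = pd.Series(dict(living_counts)).sort_index()
    if series.empty:
        raise ValueError("living-count series must be non-empty")
    target = 2.0 * initial_count
    steps = series.index.to_numpy(dtype=float)
    vals = series.to_numpy(dtype=float)
    hit = np.flatnonzero(vals >= target)
    if len(hit) == 0:
        return None
    i = hit[0]
    if i == 0:
        t = steps[0]
    else:
        t0, t1 = steps[i - 1], steps[i]
        c0, c1 = vals[i - 1], vals[i]
        t = t0 + (target - c0) / (c1 - c0) * (t1 - t0)
    return float(t / decision_window)


def clonal_fractions(snapshot: pd.DataFrame) -> dict[str, float]:
    """Fraction of *living* cells per clone in a final snapshot
    (columns: clone, status).  Fractions sum to 1."""
    living = snapshot[snapshot["status"].isin(["alive", "arrested"])]
    if len(living) == 0:
        raise ValueError("no living cells in snapshot")
    frac = living.groupby("clone").size() / len(living)
    return frac.to_dict()


def isolation_fractions(final_counts: Mapping[str, float]) -> dict[str, float]:
    """Isolation-mode clonal fractions: each clone's final living count over
    the summed finals across the separate monoclonal runs."""
    total = float(sum(final_counts.values()))
    if total <= 0:
        raise ValueError("no living cells across isolation runs")
    return {k: v / total for k, v in final_counts.items()}


def necrotic_core_size(snapshot: pd.DataFrame) -> int:
    """Number of necrotic cells in a final snapshot."""
    return int((snapshot["status"] == "necrotic").sum())


def kruskal_wallis(groups: Iterable[Sequence[float]]) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction and chi-square
    p-value; all-identical values across groups return (0, 1) by
    convention."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def significance_stars(p: float) -> str:
    for thresh, stars in [(1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")]:
        if p < thresh:
            return stars
    return ""


def standard_error(values: Sequence[float]) -> float:
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        return float("nan")
    return float(v.std(ddof=1) / math.sqrt(len(v)))
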