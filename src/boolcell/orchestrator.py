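"""Experiment execution: replicates with independent seed streams and
aggregation across repeats.

Replicate ``i`` of an experiment with master seed ``s`` draws its generator
from ``numpy.random.SeedSequence(s).spawn()`` stream ``i``, so replicates are
statistically independent, reproducible, and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import BoolcellError
from .population import CellStatus, World

_STATUS_COLS = ["alive", "arrested", "necrotic"]


@dataclass
class RunResult:
    """Per-replicate output: event log, per-step counts by clone and status,
    the final lattice snapshot, and per-substance central-voxel series."""

    replicate: int
    seed_entropy: int
    counts: pd.DataFrame  # step, clone, alive, arrested, necrotic
    events: pd.DataFrame  # step, cell_id, clone, event, i, j, k
    final_snapshot: pd.DataFrame  # cell_id, clone, status, i, j, k
    center_concentrations: pd.DataFrame  # step, substance, concentration
    steps_executed: int

    def living_series(self, clone: str | None = None) -> pd.Series:
        df = self.counts
        if clone is not None:
            df = df[df["clone"] == clone]
        living = df.assign(living=df["alive"] + df["arrested"])
        return living.groupby("step")["living"].sum()


@dataclass
class ExperimentResult:
    config: SimulationConfig
    results: list[RunResult]
    aggregate: pd.DataFrame  # step, clone, status, mean, se

    def final_living_counts(self) -> pd.Series:
        """Mean final living count per clone across replicates."""
        vals = {}
        for r in self.results:
            last = r.counts[r.counts["step"] == r.counts["step"].max()]
            for _, row in last.iterrows():
                vals.setdefault(row["clone"], []).append(
                    row["alive"] + row["arrested"]
                )
        return pd.Series({k: float(np.mean(v)) for k, v in vals.items()})


def _world_to_result(world: World, replicate: int, entropy: int) -> RunResult:
    counts = pd.DataFrame(
        world.counts_log, columns=["step", "clone"] + _STATUS_COLS
    )
    events = pd.DataFrame(
        world.events,
        columns=["step", "cell_id", "clone", "event", "i", "j", "k"],
    )
    rows = world.rows_with_status(
        CellStatus.ALIVE, CellStatus.ARRESTED, CellStatus.NECROTIC
    )
    snapshot = pd.DataFrame(
        {
            "cell_id": rows,
            "clone": [world.clone_labels[c] for c in world.clone[rows]],
            "status": [CellStatus(int(s)).name.lower() for s in world.status[rows]],
            "i": world.pos[rows, 0],
            "j": world.pos[rows, 1],
            "k": world.pos[rows, 2],
        }
    )
    center = pd.DataFrame(
        world.center_log, columns=["step", "substance", "concentration"]
    )
    return RunResult(
        replicate=replicate,
        seed_entropy=entropy,
        counts=counts,
        events=events,
        final_snapshot=snapshot,
        center_concentrations=center,
        steps_executed=world.step,
    )


def replicate_rng(config: SimulationConfig, replicate_index: int) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(replicate_index + 1)
    return np.random.default_rng(children[replicate_index])


def run_replicate(config: SimulationConfig, replicate_index: int = 0) -> RunResult:
    """Execute one replicate deterministically given (seed, index)."""
    config.validate()
    rng = replicate_rng(config, replicate_index)
    world = World(config, rng)
    world.run()
    return _world_to_result(world, replicate_index, config.seed)


def aggregate_counts(results: list[RunResult]) -> pd.DataFrame:
    """Mean and standard error (sd/sqrt(R)) of counts per step, clone and
    status across replicates.  SE is NaN for a single replicate."""
    frames = []
    for r in results:
        long = r.counts.melt(
            id_vars=["step", "clone"],
            value_vars=_STATUS_COLS,
            var_name="status",
            value_name="count",
        )
        long["replicate"] = r.replicate
        frames.append(long)
    allc = pd.concat(frames, ignore_index=True)
    grouped = allc.groupby(["step", "clone", "status"])["count"]
    agg = grouped.agg(["mean", "std", "count"]).reset_index()
    n = agg["count"]
    agg["se"] = np.where(n > 1, agg["std"] / np.sqrt(n), np.nan)
    return agg[["step", "clone", "status", "mean", "se"]]


def run_experiment(config: SimulationConfig) -> ExperimentResult:
    """Run all replicates sequentially and aggregate.

    Aggregation is a pure function of the per-replicate results, so the
    outcome is independent of execution order.
    """
    config.validate()
    results = []
    for i in range(config.replicates):
        try:
            results.append(run_replicate(config, i))
        except BoolcellError:
            raise
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise BoolcellError(
                f"replicate {i} (seed {config.seed}) failed: {exc}"
            ) from exc
    return ExperimentResult(
        config=config, results=results, aggregate=aggregate_counts(results)
    )


def run_isolation_panel(config: SimulationConfig) -> dict[str, ExperimentResult]:
    """Run each clone as a separate monoclonal experiment (full initial
    population each), as used for isolation-versus-competition comparisons."""
    out = {}
    for p in config.profiles:
        mono = p.__class__(
            clone_label=p.clone_label,
            constraints=dict(p.constraints),
            initial_fraction=1.0,
        )
        sub = config.copy(profiles=[mono], isolation=False)
        out[p.clone_label] = run_experiment(sub)
    return out


def write_result_dir(result: ExperimentResult, out_dir: str | Path) -> None:
    """Write an experiment to a directory of delimited tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.aggregate.to_csv(out / "growth_curves.csv", index=False)
    for r in result.results:
        r.counts.to_csv(out / f"counts_rep{r.replicate}.csv", index=False)
        r.events.to_csv(out / f"events_rep{r.replicate}.csv", index=False)
        r.final_snapshot.to_csv(
            out / f"snapshot_rep{r.replicate}.csv", index=False
        )
        if len(r.center_concentrations):
            r.center_concentrations.to_csv(
                out / f"fields_rep{r.replicate}.csv", index=False
            )
    manifest = {
        "replicates": result.config.replicates,
        "max_steps": result.config.max_steps,
        "initial_cells": result.config.initial_cells,
        "decision_window": result.config.decision_window,
        "seed": result.config.seed,
        "clones": [p.clone_label for p in result.config.profiles],
        "metadata": result.config.metadata,
    }
    import json

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
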