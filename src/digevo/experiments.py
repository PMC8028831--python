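"""Experiment driver, file I/O and the archetype fixture library.

The study conditions form a grid: two divide-time mutation rates
(7.5e-4 and 7.5e-3), steady-state resource levels rising by decades from 0.1
to 10,000 per site, and lattice sizes from 50 to 500, with replicate
populations each seeded by the same ancestor.  The full design (100
replicates × 100,000 updates) is cluster-scale; a desk preset covering the
corners of the grid at reduced replicate and update counts reproduces the
qualitative phenomena and is what the shipped analyses use.

The fixture library provides hand-crafted archetype genomes — replication
loops with one/two/four h-copy instructions, with and without if-label
validation, a metabolic-signaling genome and a dead genome — that stand in
for evolved genotypes when testing the assays.  Every fixture's recorded
expectations are enforced by the test suite, so the fixtures double as
regression tests for the VM semantics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from . import genetics
from .world import EventLog, PopulationSnapshot, RunConfig, SnapshotRecord, run_simulation

__all__ = [
    "ConditionGrid",
    "FixtureSpec",
    "make_fixtures",
    "fixture",
    "derive_seed",
    "run_grid",
    "write_snapshot",
    "read_snapshot",
    "write_event_log",
]

SNAPSHOT_MAGIC = "#digevo-snapshot\tv1"


@dataclass
class ConditionGrid:
    mutation_rates: tuple[float, ...] = (7.5e-4, 7.5e-3)
    resource_levels: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0)
    world_sizes: tuple[int, ...] = (50, 100, 200, 500)
    replicates: int = 100
    updates: int = 100_000
    base_seed: int = 1

    @classmethod
    def desk_preset(cls, base_seed: int = 1) -> "ConditionGrid":
        """Reduced grid for desk-scale runs: corner conditions, 10
        replicates, 20,000 updates."""
        return cls(
            resource_levels=(0.1, 100.0, 10000.0),
            world_sizes=(50, 200),
            replicates=10,
            updates=20_000,
            base_seed=base_seed,
        )

    def cells(self):
        i = 0
        for mut in self.mutation_rates:
            for rstar in self.resource_levels:
                for size in self.world_sizes:
                    yield i, mut, rstar, size
                    i += 1


def derive_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic, injective-in-practice seed for (cell, replicate)."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(cell_index, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def run_grid(grid: ConditionGrid, out_dir, ancestor=None, progress=False):
    """Execute the grid; write a manifest plus per-run logs and snapshots.

    Resumable: runs whose snapshot file already exists are skipped and their
    manifest rows preserved.  Failed or extinct replicates are flagged in
    the manifest, never dropped.
    """
    os.makedirs(out_dir, exist_ok=True)
    if ancestor is None:
        ancestor = genetics.build_ancestor()
    manifest_rows = []
    for cell_index, mut, rstar, size in grid.cells():
        for rep in range(grid.replicates):
            seed = derive_seed(grid.base_seed, cell_index, rep)
            tag = f"mut{mut:g}_r{rstar:g}_n{size}_rep{rep}"
            snap_path = os.path.join(out_dir, f"snapshot_{tag}.tsv")
            log_path = os.path.join(out_dir, f"log_{tag}.tsv")
            if not os.path.exists(snap_path):
                config = RunConfig(
                    size=size,
                    updates=grid.updates,
                    divide_mut_prob=mut,
                    rstar=rstar,
                    seed=seed,
                )
                log, snapshot, _ = run_simulation(config, ancestor)
                snapshot.meta.update({"replicate": rep, "cell_index": cell_index})
                write_snapshot(snap_path, snapshot)
                write_event_log(log_path, log)
                extinct = log.extinct
                pop = log.population[-1] if log.population else 0
            else:
                snapshot = read_snapshot(snap_path)
                extinct = len(snapshot) == 0
                pop = len(snapshot)
            manifest_rows.append(
                {
                    "cell_index": cell_index,
                    "mutation_rate": mut,
                    "rstar": rstar,
                    "size": size,
                    "replicate": rep,
                    "seed": seed,
                    "extinct": extinct,
                    "final_population": pop,
                    "snapshot": os.path.basename(snap_path),
                }
            )
            if progress:
                print(f"done {tag}: pop={pop} extinct={extinct}")
    import pandas as pd

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.tsv"), sep="\t", index=False)
    return manifest


# ---------------------------------------------------------------------------
# snapshot / log files

def write_snapshot(path, snapshot: PopulationSnapshot) -> None:
    with open(path, "w") as fh:
        fh.write(SNAPSHOT_MAGIC + "\n")
        meta = "\t".join(f"{k}={v}" for k, v in sorted(snapshot.meta.items()))
        fh.write(f"#meta\t{meta}\n")
        fh.write("cell\tgenome\tmerit\tfacing\ttask_counts\n")
        for r in snapshot.records:
            counts = ",".join(str(c) for c in r.task_counts)
            fh.write(f"{r.cell}\t{r.genome}\t{float(r.merit)!r}\t{r.facing}\t{counts}\n")


def read_snapshot(path) -> PopulationSnapshot:
    with open(path) as fh:
        magic = fh.readline().rstrip("\n")
        if magic != SNAPSHOT_MAGIC:
            raise ValueError(f"{path}: not a digevo snapshot (header {magic!r})")
        meta_line = fh.readline().rstrip("\n")
        meta = {}
        if meta_line.startswith("#meta\t"):
            for kv in meta_line.split("\t")[1:]:
                k, _, v = kv.partition("=")
                try:
                    meta[k] = int(v)
                except ValueError:
                    try:
                        meta[k] = float(v)
                    except ValueError:
                        meta[k] = v
            header = fh.readline()
        else:
            header = meta_line
        if not header.startswith("cell\t"):
            raise ValueError(f"{path}: missing column header")
        records = []
        for line in fh:
            cell, genome, merit, facing, counts = line.rstrip("\n").split("\t")
            genetics.parse(genome)  # validate
            records.append(
                SnapshotRecord(
                    cell=int(cell),
                    genome=genome,
                    merit=float(merit),
                    facing=int(facing),
                    task_counts=tuple(int(c) for c in counts.split(",")),
                )
            )
    return PopulationSnapshot(records=records, meta=meta)


def write_event_log(path, log: EventLog) -> None:
    with open(path, "w") as fh:
        fh.write("#digevo-log\tv1\n")
        fh.write("update\tbirths\tdeaths\tpopulation\tmean_merit\n")
        for row in zip(log.updates, log.births, log.deaths, log.population, log.mean_merit):
            fh.write("\t".join(str(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# fixtures

@dataclass(frozen=True)
class FixtureSpec:
    name: str
    genome: tuple[int, ...]
    expected: dict = field(default_factory=dict)


def make_fixtures() -> list[FixtureSpec]:
    """The archetype library; expectations are asserted by the test suite."""
    return [
        FixtureSpec(
            "ancestor",
            tuple(genetics.build_ancestor()),
            {
                "loop_h_copies": 1,
                "has_iflabel": True,
                "rotations": 1,
                "tasks": ("NOT",),
                "viable": True,
            },
        ),
        FixtureSpec(
            "loop-2x",
            tuple(genetics.build_loop2x()),
            {"loop_h_copies": 2, "has_iflabel": False, "viable": True},
        ),
        FixtureSpec(
            "loop-2x-iflabel",
            tuple(genetics.build_loop2x_iflabel()),
            {"loop_h_copies": 2, "has_iflabel": True, "viable": True},
        ),
        FixtureSpec(
            "loop-4x",
            tuple(genetics.build_loop4x()),
            {"loop_h_copies": 4, "has_iflabel": False, "viable": True},
        ),
        FixtureSpec(
            "messenger",
            tuple(genetics.build_messenger()),
            {
                "loop_h_copies": 1,
                "has_iflabel": True,
                "viable": True,
                "messaging_dependent": True,
                "joint_task": "NOR",
            },
        ),
        FixtureSpec("dead", tuple(genetics.build_dead()), {"viable": False}),
    ]


def fixture(name: str) -> list[int]:
    for spec in make_fixtures():
        if spec.name == name:
            return list(spec.genome)
    raise KeyError(name)
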