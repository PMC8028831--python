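"""The toroidal world and its update loop.

Organisms occupy at most one cell each on a periodic 2-D lattice; every cell
has exactly eight neighbours.  Time advances in *updates*: each update the
scheduler hands every organism a slice of CPU cycles proportional to its
merit — 30 cycles at the basal merit, more for merit above it (capped), with
largest-remainder rounding so totals are exact — then the chemostat relaxes
the resource field.  Births replace any occupant of the faced cell; organisms
die only by replacement.  Messages are delivered at send time to the target's
queue (oldest dropped beyond capacity).

Merit bookkeeping: task rewards accumulate in a bonus during gestation; at
divide the organism's merit becomes ``base × (1 + bonus)`` and the offspring
inherits it.  A single seeded RNG stream drives inputs, mutation draws and
placement, with draw order fixed by the row-major organism traversal, so runs
are exactly reproducible from (config, seed).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .environment import (
    ResourceState,
    RewardPolicy,
    chemostat_step,
    classify_output,
    consume_and_reward,
)
from .genetics import MutationConfig, apply_divide_mutations, serialize
from .instructions import GENOME_LEN, N_CODES
from .vm import DIRECTIONS, MESSAGE_QUEUE_CAP, Organism, execute_cycles

__all__ = [
    "RunConfig",
    "World",
    "EventLog",
    "PopulationSnapshot",
    "SnapshotRecord",
    "run_simulation",
    "world_dims",
]

BASE_MERIT = float(GENOME_LEN)


def world_dims(n_cells: int) -> tuple[int, int]:
    """Nearest-to-square factorization of the requested site count."""
    best = (1, n_cells)
    for h in range(1, int(n_cells**0.5) + 1):
        if n_cells % h == 0:
            best = (h, n_cells // h)
    return best


@dataclass
class RunConfig:
    """Everything a run needs; defaults follow the study conditions."""

    size: int = 50  # lattice sites (max population)
    updates: int = 100_000
    divide_mut_prob: float = 7.5e-3
    copy_mut_prob: float = 0.0
    rstar: float = 100.0
    seed: int = 0
    cycles_per_org: int = 30
    merit_ratio_cap: float = 8.0
    min_copy_fraction: float = 1.0
    uptake_fraction: float = 0.0025
    uptake_cap: float = 1.0
    outflow: float = 0.01
    diffusion: float = 0.5
    snapshot_every: int = 0  # 0: final snapshot only
    task_values: tuple | None = None  # override the task table's merit weights

    def __post_init__(self):
        for name in ("divide_mut_prob", "copy_mut_prob", "min_copy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.size < 1 or self.updates < 0:
            raise ValueError("size must be >=1 and updates >=0")

    @property
    def dims(self) -> tuple[int, int]:
        return world_dims(self.size)


@dataclass
class EventLog:
    updates: list[int] = field(default_factory=list)
    births: list[int] = field(default_factory=list)
    deaths: list[int] = field(default_factory=list)
    population: list[int] = field(default_factory=list)
    mean_merit: list[float] = field(default_factory=list)
    extinct: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "update": self.updates,
                "births": self.births,
                "deaths": self.deaths,
                "population": self.population,
                "mean_merit": self.mean_merit,
            }
        )


@dataclass(frozen=True)
class SnapshotRecord:
    cell: int
    genome: str
    merit: float
    facing: int
    task_counts: tuple[int, ...]


@dataclass
class PopulationSnapshot:
    records: list[SnapshotRecord]
    meta: dict = field(default_factory=dict)

    def genomes(self) -> list[str]:
        return [r.genome for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


class World:
    """The lattice, scheduler and event application (the VM's context)."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.height, self.width = config.dims
        n = self.height * self.width
        self.cells: list[Optional[Organism]] = [None] * n
        self.rng = random.Random(config.seed)
        self.resources = ResourceState.uniform(
            (self.height, self.width),
            config.rstar,
            outflow=config.outflow,
            diffusion=config.diffusion,
        )
        if config.task_values is not None:
            self.policy = RewardPolicy(
                config.uptake_fraction, config.uptake_cap, tuple(config.task_values)
            )
        else:
            self.policy = RewardPolicy(config.uptake_fraction, config.uptake_cap)
        self.mutation = MutationConfig(config.divide_mut_prob)
        self.copy_mut_prob = config.copy_mut_prob
        self.min_copied_sites = max(1, round(config.min_copy_fraction * GENOME_LEN))
        self.log = EventLog()
        self.update_number = 0
        self.executed_cycles = 0
        self.total_births = 0
        self.mutation_events = 0
        self.mutation_sites = 0
        self._births_this_update = 0
        self._deaths_this_update = 0
        self.snapshots: list[PopulationSnapshot] = []
        # neighbour lookup: cell -> tuple of 8 neighbour cells, facing order
        self.neighbors: list[tuple[int, ...]] = []
        for r in range(self.height):
            for c in range(self.width):
                self.neighbors.append(
                    tuple(
                        ((r + dr) % self.height) * self.width + ((c + dc) % self.width)
                        for dr, dc in DIRECTIONS
                    )
                )

    # -- population management ---------------------------------------------

    def seed_organism(self, genome: list[int], cell: int = 0, merit: float = BASE_MERIT) -> Organism:
        org = Organism(list(genome), merit=merit, facing=self.rng.randrange(8))
        org.cell = cell
        if self.cells[cell] is not None:
            self.cells[cell].alive = False
        self.cells[cell] = org
        return org

    def population(self) -> list[Organism]:
        return [o for o in self.cells if o is not None]

    # -- ExecutionContext protocol ------------------------------------------

    def random(self) -> float:
        return self.rng.random()

    def random_code(self) -> int:
        return self.rng.randrange(N_CODES)

    def next_input(self, org: Organism) -> int:
        return self.rng.getrandbits(5)

    def output(self, org: Organism, value: int) -> None:
        buf = org.cpu.input_buffer
        if not buf:
            return
        matched = classify_output(value, buf)
        if not matched:
            return
        row, col = divmod(org.cell, self.width)
        levels = self.resources.levels
        for task in matched:
            org.bonus += consume_and_reward(levels, task, row, col, self.policy)
            org.task_counts[task] += 1

    def divide(self, org: Organism, offspring: list[int]) -> None:
        merit = BASE_MERIT * (1.0 + org.bonus)
        org.merit = merit
        org.bonus = 0.0
        if self.mutation.per_site_substitution_prob > 0.0:
            genome, events = apply_divide_mutations(
                offspring, self.mutation, self.rng, count_events=True
            )
            self.mutation_events += events
        else:
            genome = offspring
        self.mutation_sites += GENOME_LEN
        target = self.neighbors[org.cell][org.facing]
        occupant = self.cells[target]
        if occupant is not None:
            occupant.alive = False
            self._deaths_this_update += 1
        child = Organism(genome, merit=merit, facing=self.rng.randrange(8))
        child.cell = target
        self.cells[target] = child
        self._births_this_update += 1
        self.total_births += 1

    def _deliver(self, target_cell: int, v1: int, v2: int) -> None:
        occupant = self.cells[target_cell]
        if occupant is None:
            return
        q = occupant.messages
        q.append((v1, v2))
        if len(q) > MESSAGE_QUEUE_CAP:
            q.popleft()

    def send(self, org: Organism, v1: int, v2: int) -> None:
        self._deliver(self.neighbors[org.cell][org.facing], v1, v2)

    def bcast(self, org: Organism, v1: int, v2: int) -> None:
        for target in self.neighbors[org.cell]:
            self._deliver(target, v1, v2)

    # -- scheduling -----------------------------------------------------------

    def _allocate(self, merits: list[float]) -> list[int]:
        """Largest-remainder allocation of CPU cycles for one update."""
        per = self.config.cycles_per_org
        cap = self.config.merit_ratio_cap
        quotas = []
        for m in merits:
            ratio = m / BASE_MERIT
            if ratio > cap:
                ratio = cap
            quotas.append(per * ratio)
        total = int(round(sum(quotas)))
        floors = [int(q) for q in quotas]
        remainder = total - sum(floors)
        if remainder > 0:
            order = sorted(
                range(len(quotas)), key=lambda i: (floors[i] - quotas[i], i)
            )
            for i in order[:remainder]:
                floors[i] += 1
        return floors

    # -- the update loop ------------------------------------------------------

    def run_update(self) -> bool:
        """One update; returns False on extinction."""
        orgs = self.population()
        if not orgs:
            self.log.extinct = True
            return False
        self._births_this_update = 0
        self._deaths_this_update = 0
        quotas = self._allocate([o.merit for o in orgs])
        for org, quota in zip(orgs, quotas):
            if org.alive and quota > 0:
                self.executed_cycles += execute_cycles(org, quota, self)
        chemostat_step(self.resources)
        self.update_number += 1
        for org in self.cells:
            if org is not None:
                org.age_updates += 1
        pop = self.population()
        self.log.updates.append(self.update_number)
        self.log.births.append(self._births_this_update)
        self.log.deaths.append(self._deaths_this_update)
        self.log.population.append(len(pop))
        self.log.mean_merit.append(sum(o.merit for o in pop) / len(pop) if pop else 0.0)
        return True

    def snapshot(self, extra_meta: dict | None = None) -> PopulationSnapshot:
        records = [
            SnapshotRecord(
                cell=i,
                genome=serialize(org.genome),
                merit=org.merit,
                facing=org.facing,
                task_counts=tuple(org.task_counts),
            )
            for i, org in enumerate(self.cells)
            if org is not None
        ]
        meta = {
            "update": self.update_number,
            "size": self.config.size,
            "mutation_rate": self.config.divide_mut_prob,
            "rstar": self.config.rstar,
            "seed": self.config.seed,
        }
        if extra_meta:
            meta.update(extra_meta)
        return PopulationSnapshot(records=records, meta=meta)


def run_simulation(
    config: RunConfig, ancestor: list[int]
) -> tuple[EventLog, PopulationSnapshot, World]:
    """Seed one ancestor at a fixed cell and iterate the update loop.

    Returns the event log, the final population snapshot (with periodic
    snapshots stored on the world when ``snapshot_every`` is set) and the
    world itself.  Extinction flags the log and returns partial results.
    """
    world = World(config)
    world.seed_organism(ancestor, cell=0)
    for _ in range(config.updates):
        if not world.run_update():
            break
        if config.snapshot_every and world.update_number % config.snapshot_every == 0:
            world.snapshots.append(world.snapshot())
    return world.log, world.snapshot(), world
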