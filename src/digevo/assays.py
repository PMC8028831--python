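"""Per-genotype measurement procedures.

Two notions of fitness coexist.  The platform-internal metric is
merit/gestation with the organism *in isolation*; it cannot see benefits
that flow between neighbours.  The assay used throughout the analyses
instead places 200 clonal copies of a genotype in a dedicated world with
mutation forced to zero, lets the population stabilize for 100 updates and
reports the mean births/update over the following 400 — so same-genotype
messaging benefits are captured by construction.

Marginal utility of a process (e.g. messaging) is the fractional fitness
lost when every instruction enabling the process is replaced by nop-X:
``(F − F_knockout) / F``, measured with the same seed and assay settings
for both genomes.

Task complexity is the minimum number of two-input NAND gates needed to
compute a task from the two inputs, found once by exhaustive circuit search.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from functools import lru_cache

from .environment import N_TASKS, TASKS, classify_output
from .genetics import build_ancestor, knockout
from .instructions import GENOME_LEN, PROCESS_GROUPS
from .vm import Organism, execute_cycles
from .world import BASE_MERIT, RunConfig, World

__all__ = [
    "AssayResult",
    "Phenotype",
    "MarginalUtility",
    "fitness_assay",
    "isolation_assay",
    "viability",
    "phenotype_profile",
    "joint_phenotype_profile",
    "marginal_utility",
    "task_complexity",
    "ancestor_gestation",
    "PROFILE_INPUT_CYCLE",
]

#: Scripted inputs for reproducible phenotype profiling.  The triple is
#: chosen so that degenerate outputs a profiled program tends to emit —
#: constant 0 and echoes of its own inputs — never coincide with any task
#: result on the buffered inputs, while NOT and NOR results stay nonzero.
PROFILE_INPUT_CYCLE = (3, 5, 9)


@dataclass(frozen=True)
class AssayResult:
    fitness: float  # births/update in the clonal-world assay (nan if not run)
    merit: float  # merit at first divide in isolation
    gestation: float  # cycles to first divide in isolation (inf if sterile)
    platform_fitness: float  # merit / gestation (0 if sterile)
    viability: float = float("nan")


@dataclass(frozen=True)
class Phenotype:
    task_vector: tuple[bool, ...]  # 9 booleans, task-table order
    task_counts: tuple[int, ...]  # performances over a single gestation

    @property
    def class_id(self) -> int:
        """0..511: the phenotype class index (bit i = task i performed)."""
        return sum(1 << i for i, b in enumerate(self.task_vector) if b)


@dataclass(frozen=True)
class MarginalUtility:
    process: str
    utility: float  # (F - F_ko)/F; nan when F == 0
    fitness: float
    fitness_knockout: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.utility)


# ---------------------------------------------------------------------------
# isolation harness

class _IsolationContext:
    """Single organism, saturating resources, no neighbours.

    Inputs come from a seeded RNG or a fixed script; task performances are
    counted and rewarded at a constant consumption (no depletion).
    """

    def __init__(self, rstar=10_000.0, seed=0, input_script=None,
                 uptake_fraction=0.0025, uptake_cap=1.0):
        self.rng = random.Random(seed)
        self.copy_mut_prob = 0.0
        self.min_copied_sites = GENOME_LEN
        self.consumed = min(uptake_fraction * rstar, uptake_cap)
        self.input_script = input_script
        self._script_pos = 0
        self.divides: list[tuple[list[int], int]] = []  # (offspring, gestation)
        self.counts_at_first_divide: tuple[int, ...] | None = None

    def random(self):
        return self.rng.random()

    def random_code(self):
        return self.rng.randrange(32)

    def next_input(self, org):
        if self.input_script is not None:
            value = self.input_script[self._script_pos % len(self.input_script)]
            self._script_pos += 1
            return value
        return self.rng.getrandbits(5)

    def output(self, org, value):
        buf = org.cpu.input_buffer
        if not buf:
            return
        for task in classify_output(value, buf):
            org.bonus += TASKS[task].value * self.consumed
            org.task_counts[task] += 1

    def divide(self, org, offspring):
        merit = BASE_MERIT * (1.0 + org.bonus)
        org.merit = merit
        org.bonus = 0.0
        if not self.divides:
            self.counts_at_first_divide = tuple(org.task_counts)
        self.divides.append((offspring, org.last_gestation))

    def send(self, org, v1, v2):
        pass

    def bcast(self, org, v1, v2):
        pass


def _run_isolated(genome, budget, ctx, stop_after_divides=1):
    org = Organism(list(genome))
    used = 0
    chunk = 256
    while used < budget and len(ctx.divides) < stop_after_divides:
        step = min(chunk, budget - used)
        used += execute_cycles(org, step, ctx)
    return org, used


@lru_cache(maxsize=1)
def ancestor_gestation() -> int:
    """Cycles the ancestral genome needs for one gestation (VM-measured)."""
    ctx = _IsolationContext()
    _run_isolated(build_ancestor(), 100_000, ctx)
    return ctx.divides[0][1]


def isolation_assay(genome, rstar=10_000.0, seed=0, budget_factor=10) -> AssayResult:
    """Merit, gestation and merit/gestation for a single isolated organism.

    Non-replicators (no divide within ``budget_factor`` × the ancestral
    gestation) get gestation ∞ and platform fitness 0.
    """
    budget = budget_factor * ancestor_gestation()
    ctx = _IsolationContext(rstar=rstar, seed=seed)
    org, _ = _run_isolated(genome, budget, ctx)
    if ctx.divides:
        gestation = ctx.divides[0][1]
        return AssayResult(
            fitness=float("nan"),
            merit=org.merit,
            gestation=float(gestation),
            platform_fitness=org.merit / gestation,
        )
    return AssayResult(
        fitness=float("nan"), merit=BASE_MERIT, gestation=float("inf"), platform_fitness=0.0
    )


def viability(genomes, rstar=10_000.0, seed=0, budget_factor=10) -> float:
    """Fraction of genomes that manage at least one divide in isolation
    under high resource within the cycle budget."""
    if not genomes:
        raise ValueError("viability of an empty genome list is undefined")
    budget = budget_factor * ancestor_gestation()
    alive = 0
    for genome in genomes:
        ctx = _IsolationContext(rstar=rstar, seed=seed)
        _run_isolated(genome, budget, ctx)
        if ctx.divides:
            alive += 1
    return alive / len(genomes)


# ---------------------------------------------------------------------------
# phenotype profiling

def phenotype_profile(genome, budget_factor=10) -> Phenotype:
    """Tasks performed over a single gestation with scripted inputs."""
    budget = budget_factor * ancestor_gestation()
    ctx = _IsolationContext(input_script=PROFILE_INPUT_CYCLE)
    org, _ = _run_isolated(genome, budget, ctx)
    counts = ctx.counts_at_first_divide
    if counts is None:  # sterile: whatever it managed within the budget
        counts = tuple(org.task_counts)
    return Phenotype(task_vector=tuple(c > 0 for c in counts), task_counts=counts)


class _PairContext(_IsolationContext):
    """Two organisms adjacent on a tiny torus; all messages reach the partner."""

    def __init__(self, **kw):
        super().__init__(**kw)
        self.partner: dict[int, Organism] = {}
        self.first_counts: dict[int, tuple[int, ...]] = {}

    def divide(self, org, offspring):
        if id(org) not in self.first_counts:
            self.first_counts[id(org)] = tuple(org.task_counts)
        super().divide(org, offspring)

    def _deliver(self, org, v1, v2):
        other = self.partner.get(id(org))
        if other is not None:
            other.messages.append((v1, v2))
            if len(other.messages) > 32:
                other.messages.popleft()

    def send(self, org, v1, v2):
        self._deliver(org, v1, v2)

    def bcast(self, org, v1, v2):
        self._deliver(org, v1, v2)


def joint_phenotype_profile(genome_a, genome_b, budget_factor=20):
    """Profile two genomes run together (facing each other, messages flowing).

    Each organism is executed in alternating 30-cycle slices until both have
    divided once (or the budget runs out); returns the two phenotypes over
    the first gestation of each.
    """
    ctx = _PairContext(input_script=PROFILE_INPUT_CYCLE)
    a = Organism(list(genome_a))
    b = Organism(list(genome_b))
    ctx.partner[id(a)] = b
    ctx.partner[id(b)] = a
    budget = budget_factor * ancestor_gestation()
    used = 0
    while used < budget:
        execute_cycles(a, 30, ctx)
        execute_cycles(b, 30, ctx)
        used += 30
        if id(a) in ctx.first_counts and id(b) in ctx.first_counts:
            break
    counts_a = ctx.first_counts.get(id(a), tuple(a.task_counts))
    counts_b = ctx.first_counts.get(id(b), tuple(b.task_counts))
    return (
        Phenotype(tuple(c > 0 for c in counts_a), counts_a),
        Phenotype(tuple(c > 0 for c in counts_b), counts_b),
    )


# ---------------------------------------------------------------------------
# the population fitness assay

def fitness_assay(
    genome,
    seed: int = 0,
    rstar: float = 10_000.0,
    world_size: int = 225,
    copies: int = 200,
    stabilize: int = 100,
    measure: int = 400,
    merit_ratio_cap: float = 8.0,
) -> float:
    """Births/update of a 200-copy clonal population, mutation forced to zero.

    Copies are placed on seeded-uniform cells of a dedicated world (225
    sites by default) with seeded-uniform facings; the population stabilizes
    for ``stabilize`` updates and the mean birth count over the next
    ``measure`` updates is returned.
    """
    config = RunConfig(
        size=world_size,
        updates=stabilize + measure,
        divide_mut_prob=0.0,
        rstar=rstar,
        seed=seed,
        merit_ratio_cap=merit_ratio_cap,
    )
    world = World(config)
    cells = world.rng.sample(range(world_size), min(copies, world_size))
    for cell in cells:
        world.seed_organism(genome, cell=cell)
    for _ in range(stabilize + measure):
        if not world.run_update():
            break
    births = world.log.births[stabilize:]
    if not births:
        return 0.0
    return sum(births) / measure


def marginal_utility(genome, process: str, seed: int = 0, **assay_kwargs) -> MarginalUtility:
    """Fractional fitness lost when a process's instructions are knocked out.

    A genome containing none of the process's instructions has utility 0 by
    definition (the knockout is the identity).  A genotype whose baseline
    assay fitness is 0 gets an undefined (NaN) utility.
    """
    ops = PROCESS_GROUPS[process]
    if not any(c in ops for c in genome):
        f = fitness_assay(genome, seed=seed, **assay_kwargs)
        return MarginalUtility(process, 0.0, f, f)
    f = fitness_assay(genome, seed=seed, **assay_kwargs)
    if f == 0.0:
        return MarginalUtility(process, float("nan"), 0.0, float("nan"))
    f_ko = fitness_assay(knockout(genome, process), seed=seed, **assay_kwargs)
    return MarginalUtility(process, (f - f_ko) / f, f, f_ko)


# ---------------------------------------------------------------------------
# task complexity

# single-bit truth tables over input combos (a,b) = (0,0),(0,1),(1,0),(1,1);
# bit i of the table is the output on combo i.
_A, _B = 0b1100, 0b1010
_TASK_TRUTHS: dict[int, tuple[int, ...]] = {
    0: (~_A & 15, ~_B & 15),  # NOT (either input)
    1: (~(_A & _B) & 15,),  # NAND
    2: (_A & _B,),  # AND
    3: ((_A | ~_B) & 15, (~_A | _B) & 15),  # ORN (either order)
    4: (_A | _B,),  # OR
    5: (_A & ~_B & 15, ~_A & _B & 15),  # ANDN (either order)
    6: (~(_A | _B) & 15,),  # NOR
    7: ((_A ^ _B) & 15,),  # XOR
    8: (~(_A ^ _B) & 15,),  # EQU
}


@lru_cache(maxsize=1)
def _complexity_table() -> tuple[int, ...]:
    """Exhaustive breadth-first search over NAND circuits (with reuse)."""
    start = frozenset((_A, _B))
    frontier = {start}
    seen = {start}
    best: dict[int, int] = {}
    depth = 0
    while len(best) < N_TASKS and depth <= 8:
        for state in frontier:
            for task, truths in _TASK_TRUTHS.items():
                if task not in best and any(t in state for t in truths):
                    best[task] = depth
        if len(best) == N_TASKS:
            break
        depth += 1
        nxt = set()
        for state in frontier:
            values = sorted(state)
            for i, f in enumerate(values):
                for g in values[i:]:
                    new = ~(f & g) & 15
                    if new not in state:
                        grown = state | {new}
                        if grown not in seen:
                            seen.add(grown)
                            nxt.add(grown)
        frontier = nxt
    return tuple(best[t] for t in range(N_TASKS))


def task_complexity(task) -> int:
    """Minimum number of two-input NAND gates composing the task's logic."""
    index = task if isinstance(task, int) else task.index
    return _complexity_table()[index]
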