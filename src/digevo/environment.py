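"""Metabolic tasks, chemostat resources and merit rewards.

The environment hands out random 5-bit numbers as substrates.  An organism
performs one of nine bitwise logic tasks by outputting, after taking in recent
inputs, the value of that task applied to one (NOT) or an ordered pair of its
buffered inputs.  Each task has a dedicated resource maintained per lattice
site by a global chemostat (fixed inflow/outflow toward a steady-state level,
plus lateral diffusion).  Performing a task consumes a fraction of the local
resource and adds ``value × consumed`` to the organism's merit multiplier,
which is applied at the next divide.

Task table (name, merit value): NOT 1, NAND 1, AND 2, ORN 2, OR 4, ANDN 4,
NOR 8, XOR 8, EQU 16.  All task logic is evaluated in 5-bit space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TaskDef",
    "TASKS",
    "TASK_INDEX",
    "N_TASKS",
    "classify_output",
    "RewardPolicy",
    "ResourceState",
    "chemostat_step",
]

_M5 = 31  # 5-bit mask


@dataclass(frozen=True)
class TaskDef:
    name: str
    value: int
    index: int


TASKS: tuple[TaskDef, ...] = tuple(
    TaskDef(name, value, i)
    for i, (name, value) in enumerate(
        [
            ("NOT", 1),
            ("NAND", 1),
            ("AND", 2),
            ("ORN", 2),
            ("OR", 4),
            ("ANDN", 4),
            ("NOR", 8),
            ("XOR", 8),
            ("EQU", 16),
        ]
    )
)
TASK_INDEX = {t.name: t.index for t in TASKS}
N_TASKS = len(TASKS)


def _pair_outputs(a: int, b: int) -> tuple[int, ...]:
    """The eight two-input task results for the ordered pair (a, b)."""
    ab = a & b
    o = a | b
    return (
        ~ab & _M5,  # NAND
        ab,  # AND
        (a | ~b) & _M5,  # ORN  (either order is checked via ordered pairs)
        o,  # OR
        a & ~b & _M5,  # ANDN
        ~o & _M5,  # NOR
        (a ^ b) & _M5,  # XOR
        ~(a ^ b) & _M5,  # EQU
    )


_pair_cache: dict[tuple[int, int], tuple[int, ...]] = {}


def classify_output(output: int, input_buffer: list[int]) -> set[int]:
    """Task indices whose logic maps buffered inputs to ``output``.

    NOT is checked against every single buffered input; two-input tasks
    against every ordered pair of inputs at distinct buffer positions.
    Empty buffer classifies nothing.
    """
    output &= _M5
    matched: set[int] = set()
    n = len(input_buffer)
    for a in input_buffer:
        if (~a & _M5) == output:
            matched.add(0)  # NOT
            break
    for i in range(n):
        a = input_buffer[i]
        for j in range(n):
            if i == j:
                continue
            b = input_buffer[j]
            key = (a, b)
            outs = _pair_cache.get(key)
            if outs is None:
                outs = _pair_outputs(a, b)
                _pair_cache[key] = outs
            for t in range(8):
                if outs[t] == output:
                    matched.add(t + 1)
    return matched


@dataclass
class RewardPolicy:
    """How task performance converts local resource into merit bonus.

    ``uptake_fraction`` of the local resource level is consumed per
    performance, capped at ``uptake_cap``; the merit multiplier applied at
    divide is ``1 + Σ value × consumed``.  ``values`` defaults to the task
    table's merit weights and may be overridden per task.
    """

    uptake_fraction: float = 0.0025
    uptake_cap: float = 1.0
    values: tuple = tuple(t.value for t in TASKS)


@dataclass
class ResourceState:
    """Per-cell, per-task resource field with chemostat dynamics.

    ``levels`` has shape (n_tasks, height, width).  ``steady_state`` is the
    chemostat target R*, ``outflow`` the per-update relaxation fraction δ and
    ``diffusion`` the per-update mixing fraction toward the 8-neighbour mean.
    """

    levels: np.ndarray
    steady_state: float
    outflow: float = 0.01
    diffusion: float = 0.5

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int],
        steady_state: float,
        outflow: float = 0.01,
        diffusion: float = 0.5,
    ) -> "ResourceState":
        levels = np.full((N_TASKS, *shape), float(steady_state))
        return cls(levels=levels, steady_state=float(steady_state), outflow=outflow, diffusion=diffusion)


def chemostat_step(res: ResourceState) -> None:
    """One update of inflow/outflow relaxation plus lateral diffusion.

    Relaxation moves each level a fraction δ toward R*; diffusion then mixes
    each cell toward the mean of its eight toroidal neighbours (conserving the
    total).  Mutates ``res.levels`` in place.
    """
    lv = res.levels
    d = res.outflow
    if d > 0:
        lv += d * (res.steady_state - lv)
    dc = res.diffusion
    if dc > 0 and lv.shape[1] * lv.shape[2] > 1:
        acc = np.zeros_like(lv)
        for dr, dcl in ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)):
            acc += np.roll(np.roll(lv, dr, axis=1), dcl, axis=2)
        lv *= 1.0 - dc
        lv += dc * (acc / 8.0)


def consume_and_reward(
    levels: np.ndarray,
    task: int,
    row: int,
    col: int,
    policy: RewardPolicy,
) -> float:
    """Deduct resource for one task performance; return the merit bonus."""
    level = float(levels[task, row, col])
    consumed = level * policy.uptake_fraction
    if consumed > policy.uptake_cap:
        consumed = policy.uptake_cap
    if consumed > 0.0:
        levels[task, row, col] = level - consumed
        return policy.values[task] * consumed
    return 0.0
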