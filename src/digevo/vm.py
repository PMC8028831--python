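"""The virtual CPU.

An organism is a 120-instruction genome executed by a small register machine:
three 32-bit registers (AX, BX, CX), two stacks, four heads into memory
(instruction pointer, read, write, flow), a 3-slot ring of recent
environmental inputs, and the label most recently copied by h-copy.

Replication works through the heads: ``h-alloc`` doubles memory to 240 sites
(offspring scratch at 120–239, filled with nop-X), ``h-copy`` moves one
instruction from the read head to the write head (with a per-copy substitution
probability), and ``h-divide`` splits off the offspring region once enough
sites have been copied.  A nop (a/b/c) immediately following an instruction
selects the register or head it acts on; runs of nops also serve as templates
for ``h-search`` / ``if-label`` via the cyclic complement A→B→C→A.

Side effects that touch the world (task output, input draws, births, messages)
are routed through an execution-context object so the same engine drives the
evolving lattice, isolation assays and test harnesses.  ``vm_step`` wraps the
engine for a single cycle and returns the emitted events.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Protocol

from .instructions import GENOME_LEN, N_CODES, OP

__all__ = [
    "Cpu",
    "Organism",
    "VmEvent",
    "ExecutionContext",
    "execute_cycles",
    "vm_step",
    "find_label",
    "complement_label",
]

_MASK32 = 0xFFFFFFFF
_NOPX = OP.NOP_X

#: Facing directions 0..7, clockwise from north-west, as (row, col) offsets.
DIRECTIONS = ((-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1))

INPUT_BUFFER_CAP = 3
MESSAGE_QUEUE_CAP = 32
STACK_CAP = 32
_LABEL_CAP = 8


class Cpu:
    """Mutable per-organism CPU state."""

    __slots__ = (
        "regs",
        "stacks",
        "active_stack",
        "heads",
        "memory",
        "copied",
        "copied_count",
        "input_buffer",
        "read_label",
        "gestation",
        "allocated",
    )

    def __init__(self, genome: list[int]):
        self.memory: list[int] = list(genome)
        self.regs: list[int] = [0, 0, 0]
        self.stacks: tuple[list[int], list[int]] = ([], [])
        self.active_stack = 0
        self.heads: list[int] = [0, 0, 0, 0]  # IP, read, write, flow
        self.copied = bytearray(GENOME_LEN)
        self.copied_count = 0
        self.input_buffer: list[int] = []
        self.read_label: list[int] = []
        self.gestation = 0
        self.allocated = False

    def reset(self) -> None:
        """Home all state; memory truncated to the parent genome region.

        Mutates in place — the engine holds aliases to these lists.
        """
        del self.memory[GENOME_LEN:]
        self.regs[:] = (0, 0, 0)
        self.stacks[0].clear()
        self.stacks[1].clear()
        self.active_stack = 0
        self.heads[:] = (0, 0, 0, 0)
        self.copied = bytearray(GENOME_LEN)
        self.copied_count = 0
        self.input_buffer.clear()
        self.read_label.clear()
        self.gestation = 0
        self.allocated = False


class Organism:
    """A genome plus CPU state, merit, facing and messaging buffers."""

    __slots__ = (
        "genome",
        "cpu",
        "merit",
        "bonus",
        "facing",
        "messages",
        "task_counts",
        "cell",
        "alive",
        "age_updates",
        "last_gestation",
        "divides",
    )

    def __init__(self, genome: list[int], merit: float = float(GENOME_LEN), facing: int = 0):
        if len(genome) != GENOME_LEN:
            raise ValueError(f"genome length {len(genome)} != {GENOME_LEN}")
        self.genome = list(genome)
        self.cpu = Cpu(self.genome)
        self.merit = merit
        self.bonus = 0.0  # merit-multiplier bonus accumulated this gestation
        self.facing = facing
        self.messages: deque[tuple[int, int]] = deque()
        self.task_counts = [0] * 9
        self.cell = -1
        self.alive = True
        self.age_updates = 0
        self.last_gestation = 0  # cycles of the most recent completed gestation
        self.divides = 0


@dataclass(frozen=True)
class VmEvent:
    kind: str  # output | input | copy | divide_request | message_out | broadcast_out | rotate
    payload: tuple = field(default_factory=tuple)


class ExecutionContext(Protocol):
    """What the engine needs from the world (or an assay harness)."""

    copy_mut_prob: float
    min_copied_sites: int

    def next_input(self, org: Organism) -> int: ...  # fresh 5-bit value
    def output(self, org: Organism, value: int) -> None: ...  # task check + reward
    def divide(self, org: Organism, offspring: list[int]) -> None: ...
    def send(self, org: Organism, v1: int, v2: int) -> None: ...
    def bcast(self, org: Organism, v1: int, v2: int) -> None: ...
    def random(self) -> float: ...  # uniform [0,1) for copy mutation
    def random_code(self) -> int: ...  # uniform opcode draw


def complement_label(label: list[int]) -> list[int]:
    """Cyclic nop complement: A->B, B->C, C->A."""
    return [(c + 1) % 3 for c in label]


def find_label(memory: list[int], start: int, label: list[int]) -> int:
    """Position of the first occurrence of the *complement* of ``label``,
    scanning forward from ``start`` with wraparound.

    Returns the match start, or -1 if absent.  An empty label returns
    ``start`` itself (the position just after the searching instruction,
    when called the way h-search calls it).
    """
    size = len(memory)
    if not label:
        return start % size
    target = complement_label(label)
    tlen = len(target)
    for off in range(size):
        pos = (start + off) % size
        for k in range(tlen):
            if memory[(pos + k) % size] != target[k]:
                break
        else:
            return pos
    return -1


def _read_template(memory: list[int], pos: int, size: int) -> list[int]:
    """Consecutive nops (a/b/c) starting at ``pos``."""
    out = []
    while len(out) < size:
        code = memory[(pos + len(out)) % size]
        if code > 2:
            break
        out.append(code)
    return out


def execute_cycles(org: Organism, n_cycles: int, ctx: ExecutionContext) -> int:
    """Run up to ``n_cycles`` instruction executions; returns cycles used.

    Exactly one instruction is consumed per cycle; nop modifiers and templates
    are read without separate cost.  Stops early only if the organism dies.
    """
    cpu = org.cpu
    regs = cpu.regs
    heads = cpu.heads
    cycles = 0
    while cycles < n_cycles:
        if not org.alive:
            break
        cycles += 1
        cpu.gestation += 1
        mem = cpu.memory
        size = len(mem)
        ip = heads[0] % size
        op = mem[ip]
        nxt = ip + 1

        if op <= 2 or op == 26 or op >= N_CODES:  # nop-A/B/C, nop-X, corrupt
            pass

        elif op == 21:  # h-copy
            rh = heads[1] % size
            wh = heads[2] % size
            inst = mem[rh]
            if ctx.copy_mut_prob > 0.0 and ctx.random() < ctx.copy_mut_prob:
                inst = ctx.random_code()
            mem[wh] = inst
            if cpu.allocated and wh >= GENOME_LEN:
                idx = wh - GENOME_LEN
                if not cpu.copied[idx]:
                    cpu.copied[idx] = 1
                    cpu.copied_count += 1
            if inst <= 2:
                cpu.read_label.append(inst)
                if len(cpu.read_label) > _LABEL_CAP:
                    del cpu.read_label[0]
            else:
                cpu.read_label.clear()
            heads[1] = (rh + 1) % size
            heads[2] = (wh + 1) % size

        elif op == 5:  # if-label
            template = _read_template(mem, nxt % size, size)
            nxt += len(template)
            label = cpu.read_label
            match = False
            if template:
                target = complement_label(template)
                tl = len(target)
                match = len(label) >= tl and label[-tl:] == target
            if not match:
                nxt += 1  # skip the guarded instruction

        elif op == 6:  # mov-head
            code = mem[nxt % size]
            h = code if code <= 2 else 0
            if code <= 2:
                nxt += 1
            if h == 0:
                nxt = heads[3]  # IP lands on the flow head, no auto-advance
            else:
                heads[h] = heads[3] % size

        elif op == 24:  # IO
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            ctx.output(org, regs[r] & 31)
            value = ctx.next_input(org)
            buf = cpu.input_buffer
            buf.append(value)
            if len(buf) > INPUT_BUFFER_CAP:
                del buf[0]
            regs[r] = value

        elif op == 25:  # h-search
            template = _read_template(mem, nxt % size, size)
            nxt += len(template)
            if not template:
                heads[3] = nxt % size
                regs[1] = 0
                regs[2] = 0
            else:
                pos = find_label(mem, nxt % size, template)
                if pos < 0:
                    heads[3] = ip
                    regs[1] = 0
                    regs[2] = 0
                else:
                    heads[3] = (pos + len(template)) % size
                    regs[1] = (pos - (nxt % size)) % size
                    regs[2] = len(template)

        elif op == 22:  # h-alloc
            if not cpu.allocated:
                mem.extend([_NOPX] * GENOME_LEN)
                cpu.allocated = True
                cpu.copied = bytearray(GENOME_LEN)
                cpu.copied_count = 0
                heads[2] = GENOME_LEN  # write head at the offspring region

        elif op == 23:  # h-divide
            if cpu.allocated and cpu.copied_count >= ctx.min_copied_sites:
                offspring = mem[GENOME_LEN : 2 * GENOME_LEN]
                org.last_gestation = cpu.gestation
                org.divides += 1
                cpu.reset()
                cpu.memory[:] = org.genome  # undo any wrap-around tape damage
                ctx.divide(org, offspring)
                heads[0] = 0
                continue  # fresh gestation; IP already homed

        elif op == 3:  # if-n-equ
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            if regs[r] == regs[(r + 1) % 3]:
                nxt += 1

        elif op == 4:  # if-less
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            if regs[r] >= regs[(r + 1) % 3]:
                nxt += 1

        elif op == 7:  # jmp-head
            code = mem[nxt % size]
            h = code if code <= 2 else 0
            if code <= 2:
                nxt += 1
            heads[h] = (heads[h] + regs[2]) % size
            if h == 0:
                nxt = heads[0]

        elif op == 8:  # get-head
            code = mem[nxt % size]
            h = code if code <= 2 else 0
            if code <= 2:
                nxt += 1
            regs[2] = heads[h] % size

        elif op == 9:  # set-flow
            code = mem[nxt % size]
            r = code if code <= 2 else 2
            if code <= 2:
                nxt += 1
            heads[3] = regs[r] % size

        elif op == 10:  # shift-r
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] >>= 1

        elif op == 11:  # shift-l
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] = (regs[r] << 1) & _MASK32

        elif op == 12:  # inc
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] = (regs[r] + 1) & _MASK32

        elif op == 13:  # dec
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] = (regs[r] - 1) & _MASK32

        elif op == 14:  # push
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            stack = cpu.stacks[cpu.active_stack]
            stack.append(regs[r])
            if len(stack) > STACK_CAP:
                del stack[0]

        elif op == 15:  # pop
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            stack = cpu.stacks[cpu.active_stack]
            regs[r] = stack.pop() if stack else 0

        elif op == 16:  # swap-stk
            cpu.active_stack ^= 1

        elif op == 17:  # swap
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            o = (r + 1) % 3
            regs[r], regs[o] = regs[o], regs[r]

        elif op == 18:  # add
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] = (regs[1] + regs[2]) & _MASK32

        elif op == 19:  # sub
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] = (regs[1] - regs[2]) & _MASK32

        elif op == 20:  # nand
            code = mem[nxt % size]
            r = code if code <= 2 else 1
            if code <= 2:
                nxt += 1
            regs[r] = ~(regs[1] & regs[2]) & _MASK32

        elif op == 27:  # send-msg
            ctx.send(org, regs[1], regs[2])

        elif op == 28:  # retrieve-msg
            if org.messages:
                regs[1], regs[2] = org.messages.popleft()

        elif op == 29:  # bcast1
            ctx.bcast(org, regs[1], regs[2])

        elif op == 30:  # rotate-left-one
            org.facing = (org.facing - 1) % 8

        elif op == 31:  # rotate-right-one
            org.facing = (org.facing + 1) % 8

        heads[0] = nxt % len(cpu.memory)
    return cycles


class _Recorder:
    """Context wrapper that records VmEvents while delegating to a base ctx."""

    def __init__(self, base: ExecutionContext):
        self.base = base
        self.events: list[VmEvent] = []
        self.copy_mut_prob = base.copy_mut_prob
        self.min_copied_sites = base.min_copied_sites

    def next_input(self, org):
        value = self.base.next_input(org)
        self.events.append(VmEvent("input", (value,)))
        return value

    def output(self, org, value):
        self.events.append(VmEvent("output", (value,)))
        self.base.output(org, value)

    def divide(self, org, offspring):
        self.events.append(VmEvent("divide_request", (tuple(offspring),)))
        self.base.divide(org, offspring)

    def send(self, org, v1, v2):
        self.events.append(VmEvent("message_out", (v1, v2)))
        self.base.send(org, v1, v2)

    def bcast(self, org, v1, v2):
        self.events.append(VmEvent("broadcast_out", (v1, v2)))
        self.base.bcast(org, v1, v2)

    def random(self):
        return self.base.random()

    def random_code(self):
        return self.base.random_code()


def vm_step(org: Organism, ctx: ExecutionContext) -> list[VmEvent]:
    """Execute exactly one instruction; return the events it emitted.

    Copy and rotate events are synthesized from state changes so a single
    engine serves both the fast path and the event-level contract.
    """
    rec = _Recorder(ctx)
    facing_before = org.facing
    mem = org.cpu.memory
    op = mem[org.cpu.heads[0] % len(mem)]
    execute_cycles(org, 1, rec)
    if org.facing != facing_before:
        rec.events.append(VmEvent("rotate", (org.facing,)))
    if op == OP.H_COPY:
        wh = (org.cpu.heads[2] - 1) % len(org.cpu.memory)
        rec.events.append(VmEvent("copy", (wh, org.cpu.memory[wh])))
    return rec.events
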