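"""The 32-symbol instruction set.

Each genome site holds one of 32 instructions, written as a single character
(``a``–``z`` plus ``A``–``F``).  The lowercase letters follow the canonical
"heads" virtual-CPU set (nop-A/B/C, conditionals, head movement, arithmetic,
stack ops, and the replication instructions h-copy/h-alloc/h-divide/h-search);
the uppercase letters add the null instruction nop-X, the three messaging
instructions and the two rotation instructions.

The authoritative code ↔ semantics mapping is shipped as a data file
(``data/instructions.tsv``) so that the virtual CPU and the documentation
share one table.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "ALPHABET",
    "GENOME_LEN",
    "N_CODES",
    "INSTRUCTIONS",
    "CODE_OF",
    "NAME_OF",
    "OP",
    "InstructionInfo",
]

#: One character per instruction, in opcode order 0..31.
ALPHABET = "abcdefghijklmnopqrstuvwxyzABCDEF"

#: Fixed genome length in instruction-sites; substitutions only, so conserved.
GENOME_LEN = 120

N_CODES = 32


@dataclass(frozen=True)
class InstructionInfo:
    code: str
    opcode: int
    name: str
    operand: str
    summary: str


def _load_table() -> list[InstructionInfo]:
    text = resources.files("digevo").joinpath("data/instructions.tsv").read_text()
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    if len(rows) != N_CODES:
        raise RuntimeError(f"instruction table has {len(rows)} rows, expected {N_CODES}")
    table = []
    for row in rows:
        code = row["code"]
        table.append(
            InstructionInfo(
                code=code,
                opcode=ALPHABET.index(code),
                name=row["name"],
                operand=row["operand"],
                summary=row["summary"],
            )
        )
    table.sort(key=lambda info: info.opcode)
    return table


INSTRUCTIONS: list[InstructionInfo] = _load_table()

#: instruction name -> opcode
CODE_OF: dict[str, int] = {info.name: info.opcode for info in INSTRUCTIONS}

#: opcode -> instruction name
NAME_OF: dict[int, str] = {info.opcode: info.name for info in INSTRUCTIONS}


class OP:
    """Opcode constants (module-level ints keep the VM dispatch cheap)."""

    NOP_A = 0
    NOP_B = 1
    NOP_C = 2
    IF_N_EQU = 3
    IF_LESS = 4
    IF_LABEL = 5
    MOV_HEAD = 6
    JMP_HEAD = 7
    GET_HEAD = 8
    SET_FLOW = 9
    SHIFT_R = 10
    SHIFT_L = 11
    INC = 12
    DEC = 13
    PUSH = 14
    POP = 15
    SWAP_STK = 16
    SWAP = 17
    ADD = 18
    SUB = 19
    NAND = 20
    H_COPY = 21
    H_ALLOC = 22
    H_DIVIDE = 23
    IO = 24
    H_SEARCH = 25
    NOP_X = 26
    SEND_MSG = 27
    RETRIEVE_MSG = 28
    BCAST1 = 29
    ROTATE_L = 30
    ROTATE_R = 31


# Sanity: the assignments the platform fixes must hold.
assert CODE_OF["if-label"] == ALPHABET.index("f")
assert CODE_OF["h-copy"] == ALPHABET.index("v")
assert CODE_OF["h-divide"] == ALPHABET.index("x")
assert CODE_OF["h-search"] == ALPHABET.index("z")
assert CODE_OF["nop-X"] == ALPHABET.index("A")
assert CODE_OF["send-msg"] == ALPHABET.index("B")
assert CODE_OF["retrieve-msg"] == ALPHABET.index("C")
assert CODE_OF["bcast1"] == ALPHABET.index("D")
assert CODE_OF["rotate-left-one"] == ALPHABET.index("E")
assert CODE_OF["rotate-right-one"] == ALPHABET.index("F")

#: Instruction groups used by knockout experiments.
MESSAGING_OPS = frozenset({OP.SEND_MSG, OP.RETRIEVE_MSG, OP.BCAST1})
COPYING_OPS = frozenset({OP.H_COPY})
ROTATION_OPS = frozenset({OP.ROTATE_L, OP.ROTATE_R})

PROCESS_GROUPS: dict[str, frozenset[int]] = {
    "messaging": MESSAGING_OPS,
    "copying": COPYING_OPS,
    "rotation": ROTATION_OPS,
}
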