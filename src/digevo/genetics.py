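"""Genome construction, serialization, mutation and surgery.

Genomes are fixed-length sequences of 120 instruction codes; mutation is
substitution-only (a per-site uniform redraw applied once, at divide), so
length is conserved for ever.  This module builds the ancestral replicator
and a library of hand-crafted archetype genomes (multi-h-copy loops with and
without if-label validation, a messaging genome, a dead genome) that stand in
for evolved genotypes in assay tests, and implements the surgical operations
used by the transplant and knockout experiments.

Genome files hold one 120-character line per genome; ``#`` starts a comment.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .instructions import ALPHABET, GENOME_LEN, N_CODES, OP, PROCESS_GROUPS

__all__ = [
    "MutationConfig",
    "GenomeRegion",
    "parse",
    "serialize",
    "read_genome_file",
    "write_genome_file",
    "apply_divide_mutations",
    "build_ancestor",
    "build_loop2x",
    "build_loop2x_iflabel",
    "build_loop4x",
    "build_messenger",
    "build_dead",
    "locate_copy_loop",
    "transplant_copy_loop",
    "knockout",
]

_CODE_OF_CHAR = {ch: i for i, ch in enumerate(ALPHABET)}


@dataclass(frozen=True)
class MutationConfig:
    """Per-site substitution probability applied at divide."""

    per_site_substitution_prob: float = 7.5e-3

    def __post_init__(self):
        p = self.per_site_substitution_prob
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"substitution probability {p} outside [0, 1]")


@dataclass(frozen=True)
class GenomeRegion:
    """0-based half-open interval over the 120-site sequence."""

    start: int
    end: int
    role: str = "other"  # copy-loop | internalized-copy-elements | other

    def __post_init__(self):
        if not (0 <= self.start <= self.end <= GENOME_LEN):
            raise ValueError(f"bad region [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def empty(self) -> bool:
        return self.start == self.end


# ---------------------------------------------------------------------------
# serialization

def parse(text: str) -> list[int]:
    """Letter-string -> genome (list of opcodes).  Strict: exactly 120 codes."""
    text = text.strip()
    if len(text) != GENOME_LEN:
        raise ValueError(f"genome string has {len(text)} characters, expected {GENOME_LEN}")
    genome = []
    for i, ch in enumerate(text):
        code = _CODE_OF_CHAR.get(ch)
        if code is None:
            raise ValueError(f"invalid instruction character {ch!r} at position {i}")
        genome.append(code)
    return genome


def serialize(genome: list[int]) -> str:
    if len(genome) != GENOME_LEN:
        raise ValueError(f"genome length {len(genome)} != {GENOME_LEN}")
    return "".join(ALPHABET[c] for c in genome)


def read_genome_file(path) -> list[list[int]]:
    genomes = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                genomes.append(parse(line))
    return genomes


def write_genome_file(path, genomes, comments=()) -> None:
    with open(path, "w") as fh:
        for comment in comments:
            fh.write(f"# {comment}\n")
        for g in genomes:
            fh.write(serialize(g) + "\n")


# ---------------------------------------------------------------------------
# mutation

def apply_divide_mutations(
    genome: list[int],
    cfg: MutationConfig,
    rng: random.Random,
    count_events: bool = False,
):
    """Divide-time whole-genome substitution pass.

    Each site is independently redrawn (uniformly over all 32 codes, self-
    substitution allowed) with the configured probability; the configured
    rate is therefore the substitution-*event* rate, not the observed-change
    rate.  Returns the mutated genome, or ``(genome, n_events)`` when
    ``count_events`` is set.
    """
    p = cfg.per_site_substitution_prob
    events = 0
    if p <= 0.0:
        out = list(genome)
    elif p >= 1.0:
        out = [rng.randrange(N_CODES) for _ in genome]
        events = len(genome)
    else:
        out = list(genome)
        rnd = rng.random
        for i in range(len(out)):
            if rnd() < p:
                out[i] = rng.randrange(N_CODES)
                events += 1
    if count_events:
        return out, events
    return out


# ---------------------------------------------------------------------------
# genome construction
#
# All constructed replicators share the canonical head block
#
#     h-alloc; h-search c a; mov-head c        (write head -> offspring region)
#
# and end with a template label ``a b`` that the initial h-search targets.
# The terminal copy-loop variants differ in h-copy count and in whether an
# if-label guards the divide; divides only complete once every offspring site
# has been written, so loops lacking the if-label guard simply attempt the
# divide every iteration until copying is complete.

_HEAD = "wzcagc"  # alloc, search(c a), mov-head(c)
_NOT_BLOCK = "yopcuy"  # input A; push; pop->CX; nand => ~A; output (NOT) & input B
_ROTATE = "E"


def _assemble(head: str, body: str, loop: str) -> list[int]:
    filler = GENOME_LEN - len(head) - len(body) - len(loop)
    if filler < 0:
        raise ValueError("genome blocks exceed 120 sites")
    return parse(head + body + "c" * filler + loop)


def build_ancestor() -> list[int]:
    """The ancestral seed genome.

    A single-h-copy terminal copy-loop validated by if-label, a primitive
    NOT-performing metabolic block (the simplest task in the environment) and
    exactly one rotation instruction; nop-C filler elsewhere.
    """
    return _assemble(_HEAD, _NOT_BLOCK + _ROTATE, "zvfcaxgab")


def build_loop2x() -> list[int]:
    """Two h-copy instructions per loop iteration, no if-label validation."""
    return _assemble(_HEAD, _NOT_BLOCK + _ROTATE, "zvvxgab")


def build_loop2x_iflabel() -> list[int]:
    """Two h-copy instructions per iteration, divide guarded by if-label."""
    return _assemble(_HEAD, _NOT_BLOCK + _ROTATE, "zvvfcaxgab")


def build_loop4x() -> list[int]:
    """Four h-copy instructions per iteration, no if-label validation."""
    return _assemble(_HEAD, _NOT_BLOCK + _ROTATE, "zvvvvxgab")


def build_messenger() -> list[int]:
    """A metabolic-signaling genome (role-symmetric requester/responder).

    Per gestation it reads two inputs A, B and broadcasts them; drains its
    message queue keeping the most recent pair (x, y); computes NOR(x, y)
    with a NAND cascade and broadcasts the result; zeroes its registers (so
    that in isolation it cannot output a function of its own inputs); then
    late in gestation retrieves again and outputs what it retrieved.  When a
    neighbour answered its own broadcast, that output is NOR(A, B) — a task
    the genome never completes alone.  Every late output is guarded by
    if-n-equ on freshly zeroed registers, so it only fires when a retrieve
    actually delivered a message — with messaging knocked out the genome
    emits nothing in this phase.  Replication uses the ancestral
    single-h-copy if-label-guarded loop.
    """
    body = (
        "y"      # BX <- A                      buffer [A]
        "o"      # push A
        "y"      # output A (never a task); BX <- B; buffer [A, B]
        "pc"     # pop -> CX = A
        "D"      # broadcast request (B, A)
        "CCCCCCCC"  # drain up to 8 messages; (BX, CX) <- most recent pair (x, y)
        # --- NOR(x, y) via four NANDs ---------------------------------
        "o"      # push x                        [x]
        "r"      # swap: BX=y, CX=x
        "o"      # push y                        [x, y]
        "pc"     # CX <- y                       [x]
        "u"      # BX <- ~y
        "r"      # swap: BX=y, CX=~y
        "p"      # BX <- x                       []
        "oc"     # push ~y                       [~y]
        "o"      # push x                        [~y, x]
        "pc"     # CX <- x                       [~y]
        "u"      # BX <- ~x
        "pc"     # CX <- ~y                      []
        "u"      # BX <- ~(~x & ~y) = x|y
        "o"      # push x|y                      [x|y]
        "pc"     # CX <- x|y                     []
        "u"      # BX <- NOR(x, y)
        "D"      # broadcast response (NOR, x|y)
        "p"      # BX <- 0 (stack empty): forget own-input derived values
        "pc"     # CX <- 0
        + "c" * 24  # pause while responses circulate
        + "Cdy"  # retrieve; if BX != CX a message arrived: output it
        "ppcCdy"   # re-zero registers, retrieve, guarded output
        "ppcCdy"   # and a third guarded slot
        "CCCC"   # extra drains keep the queue fresh across gestations
    )
    return _assemble(_HEAD, body, "zvfcaxgab")


def build_dead() -> list[int]:
    """All nop-X: executes forever, never copies, never divides."""
    return [OP.NOP_X] * GENOME_LEN


# ---------------------------------------------------------------------------
# structural analysis and surgery

def locate_copy_loop(genome: list[int]) -> GenomeRegion:
    """Locate the terminal copy-loop: the last h-search whose loop body
    starts before the final h-divide, through the genome end.

    Genomes with no such structure (no h-divide, or no h-copy after the
    h-search) get an empty region — the copy-loop-less archetype.
    """
    xs = [i for i, c in enumerate(genome) if c == OP.H_DIVIDE]
    if not xs:
        return GenomeRegion(0, 0, "other")
    last_x = xs[-1]
    for z in range(GENOME_LEN - 1, -1, -1):
        if genome[z] != OP.H_SEARCH:
            continue
        body = z + 1
        while body < GENOME_LEN and genome[body] <= 2:
            body += 1  # skip the search template
        if body <= last_x and any(genome[i] == OP.H_COPY for i in range(z, GENOME_LEN)):
            return GenomeRegion(z, GENOME_LEN, "copy-loop")
    return GenomeRegion(0, 0, "other")


def transplant_copy_loop(recipient: list[int], donor: list[int]) -> list[int]:
    """Replace the recipient's copy-loop region with the donor's.

    The donor loop is re-anchored at the genome end (loops are terminal
    structures); the junction is trimmed or padded with nop-X so the result
    is exactly 120 sites.  A self-transplant is the identity.  A recipient
    with no copy-loop simply has the donor loop written over its tail.
    """
    donor_region = locate_copy_loop(donor)
    if donor_region.empty:
        raise ValueError("donor genome has no copy-loop to transplant")
    loop = donor[donor_region.start : donor_region.end]
    rec_region = locate_copy_loop(recipient)
    keep = min(rec_region.start if not rec_region.empty else GENOME_LEN, GENOME_LEN - len(loop))
    out = list(recipient[:keep])
    pad = GENOME_LEN - keep - len(loop)
    out.extend([OP.NOP_X] * pad)
    out.extend(loop)
    return out


def knockout(genome: list[int], instructions) -> list[int]:
    """Replace every occurrence of the named instructions with nop-X.

    ``instructions`` is a set of opcodes or a named process group
    ("messaging", "copying", "rotation").  Idempotent, length-preserving.
    """
    if isinstance(instructions, str):
        ops = PROCESS_GROUPS[instructions]
    else:
        ops = frozenset(instructions)
    return [OP.NOP_X if c in ops else c for c in genome]
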