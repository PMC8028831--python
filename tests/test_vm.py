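"""Virtual-CPU semantics: single instructions, labels, copying, division."""

import random

import pytest

from conftest import HarnessCtx, run_until_divide
from digevo.genetics import build_ancestor, parse, serialize
from digevo.instructions import ALPHABET, GENOME_LEN, OP
from digevo.vm import Organism, complement_label, execute_cycles, find_label, vm_step


def make_org(prefix: str) -> Organism:
    """Organism whose genome starts with ``prefix`` and pads with nop-X."""
    codes = [ALPHABET.index(ch) for ch in prefix]
    return Organism(codes + [OP.NOP_X] * (GENOME_LEN - len(codes)))


@pytest.mark.parametrize(
    "program,cycles,reg,expected",
    [
        ("m", 1, 1, 1),  # inc BX
        ("mmm", 3, 1, 3),
        ("ma", 1, 0, 1),  # inc nop-A -> AX
        ("n", 1, 1, 2**32 - 1),  # dec wraps
        ("ml", 2, 1, 2),  # inc, shift-l
        ("mlk", 3, 1, 1),  # ... then shift-r
        ("u", 1, 1, 2**32 - 1),  # nand(0,0) = ~0
        ("ms", 2, 1, 1),  # add: BX = BX + CX = 1
        ("mt", 2, 1, 1),  # sub: BX - CX = 1
    ],
)
def test_single_instruction_register_semantics(program, cycles, reg, expected, harness):
    org = make_org(program)
    execute_cycles(org, cycles, harness)
    assert org.cpu.regs[reg] == expected


def test_push_pop_roundtrip_and_empty_pop(harness):
    org = make_org("mopc")  # inc; push BX; pop -> CX
    execute_cycles(org, 3, harness)
    assert org.cpu.regs[2] == 1 and org.cpu.regs[1] == 1
    org2 = make_org("p")  # pop empty stack -> 0
    org2.cpu.regs[1] = 77
    execute_cycles(org2, 1, harness)
    assert org2.cpu.regs[1] == 0


def test_swap_exchanges_bx_cx(harness):
    org = make_org("mr")
    execute_cycles(org, 2, harness)
    assert org.cpu.regs[1] == 0 and org.cpu.regs[2] == 1


@pytest.mark.parametrize("inst,facing,expected", [("F", 3, 4), ("E", 3, 2), ("E", 0, 7)])
def test_rotation(inst, facing, expected, harness):
    org = make_org(inst)
    org.facing = facing
    execute_cycles(org, 1, harness)
    assert org.facing == expected


def test_io_emits_output_then_loads_fresh_input(harness):
    org = make_org("y")
    org.cpu.regs[1] = 27
    events = vm_step(org, harness)
    kinds = [e.kind for e in events]
    assert kinds == ["output", "input"]
    assert events[0].payload == (27,)
    assert org.cpu.regs[1] == events[1].payload[0] == 3  # first scripted input
    assert org.cpu.input_buffer == [3]


def test_input_buffer_is_a_three_slot_ring(harness):
    org = make_org("yyyy")
    execute_cycles(org, 4, harness)
    # script cycles 3,5,9 -> fourth input (3) evicts the oldest
    assert org.cpu.input_buffer == [5, 9, 3]


def test_retrieve_on_empty_queue_is_a_noop(harness):
    org = make_org("C")
    org.cpu.regs[1], org.cpu.regs[2] = 7, 9
    execute_cycles(org, 1, harness)
    assert org.cpu.regs[1] == 7 and org.cpu.regs[2] == 9


def test_message_fifo_retrieval(harness):
    org = make_org("CC")
    org.messages.extend([(12, 7), (1, 2)])
    execute_cycles(org, 1, harness)
    assert (org.cpu.regs[1], org.cpu.regs[2]) == (12, 7)
    execute_cycles(org, 1, harness)
    assert (org.cpu.regs[1], org.cpu.regs[2]) == (1, 2)


def test_send_and_broadcast_carry_bx_cx(harness):
    org = make_org("mrmBD")  # inc; swap (CX=1); inc (BX=1); send; bcast
    execute_cycles(org, 5, harness)
    assert harness.sent == [(1, 1)]
    assert harness.bcasts == [(1, 1)]


def test_unknown_code_executes_as_nop(harness):
    org = make_org("m")
    org.cpu.memory[0] = 55  # corrupt
    execute_cycles(org, 1, harness)
    assert org.cpu.regs == [0, 0, 0]
    assert org.cpu.heads[0] == 1


# ---------------------------------------------------------------------------
# labels and search

def test_complement_is_cyclic():
    assert complement_label([0, 1, 2]) == [1, 2, 0]


def test_find_label_complement_rule():
    mem = [OP.NOP_X] * 100
    mem[57], mem[58] = 1, 2  # "b c"
    # searching for label "a b" finds its complement "b c" at 57
    assert find_label(mem, 0, [0, 1]) == 57


def test_find_label_empty_label_returns_start():
    assert find_label([OP.NOP_X] * 10, 4, []) == 4


def test_find_label_nearest_occurrence_wins_brute_force():
    rng = random.Random(9)
    for _ in range(50):
        mem = [rng.randrange(32) for _ in range(60)]
        start = rng.randrange(60)
        label = [rng.randrange(3) for _ in range(rng.randrange(1, 3))]
        target = complement_label(label)
        # brute-force oracle: first match scanning forward with wraparound
        expected = -1
        for off in range(60):
            pos = (start + off) % 60
            if all(mem[(pos + k) % 60] == target[k] for k in range(len(target))):
                expected = pos
                break
        assert find_label(mem, start, label) == expected


def test_h_search_empty_template_sets_flow_after_instruction(harness):
    org = make_org("zm")
    execute_cycles(org, 1, harness)
    assert org.cpu.heads[3] == 1


def test_h_search_missing_label_leaves_flow_at_ip(harness):
    org = make_org("zab")  # template "a b"; complement "b c" absent
    execute_cycles(org, 1, harness)
    assert org.cpu.heads[3] == 0


# ---------------------------------------------------------------------------
# copying and division

def test_h_copy_zero_rate_is_identity(harness):
    org = make_org("wv")
    execute_cycles(org, 2, harness)
    assert org.cpu.memory[GENOME_LEN] == org.genome[0]
    assert org.cpu.heads[1] == 1 and org.cpu.heads[2] == GENOME_LEN + 1


def test_h_copy_forced_mutation_draws_uniform_code():
    ctx = HarnessCtx(copy_mut_prob=1.0)
    org = make_org("wv")
    execute_cycles(org, 2, ctx)
    assert ctx.code_draws == 1
    assert 0 <= org.cpu.memory[GENOME_LEN] < 32


@pytest.mark.parametrize("rate", [7.5e-4, 7.5e-3])
def test_copy_mutation_event_frequency_matches_rate(rate):
    """Empirical substitution-event frequency over >=1e5 h-copy executions
    stays within 3 binomial standard errors of the configured rate."""
    ctx = HarnessCtx(copy_mut_prob=rate, seed=12345)
    genome = build_ancestor()
    while ctx.random_calls < 100_000:
        org = Organism(list(genome))
        execute_cycles(org, 1000, ctx)  # fresh organism: tape stays healthy
    n, k = ctx.random_calls, ctx.code_draws
    se = (rate * (1 - rate) / n) ** 0.5
    assert abs(k / n - rate) <= 3 * se


def test_divide_without_alloc_is_a_noop(harness):
    org = make_org("x")
    execute_cycles(org, 1, harness)
    assert not harness.divides and org.cpu.heads[0] == 1


def test_divide_requires_full_offspring_copy(harness):
    # alloc then immediate divide: nothing copied, instruction is a no-op
    org = make_org("wx")
    execute_cycles(org, 2, harness)
    assert not harness.divides


def test_ancestor_gestation_matches_hand_trace(harness):
    """The ancestral genome's cycle count to first divide, traced by hand:

    9 head/metabolic executions + 98 filler nops + 1 loop h-search +
    120 loop iterations x 3 executions = 468 cycles.
    """
    org, ctx = run_until_divide(build_ancestor(), harness)
    assert ctx.divides[0][1] == 468


def test_ancestor_copies_all_120_sites_then_divides():
    ctx = HarnessCtx()
    org = Organism(build_ancestor())
    copies = 0
    while not ctx.divides:
        events = vm_step(org, ctx)
        copies += sum(1 for e in events if e.kind == "copy")
    assert copies == GENOME_LEN
    offspring = ctx.divides[0][0]
    assert offspring == org.genome  # faithful copy at zero mutation


def test_if_label_blocks_premature_divide(harness):
    """The guarded divide in the ancestral loop never fires mid-copy."""
    org = Organism(build_ancestor())
    execute_cycles(org, 400, harness)  # deep in the copy loop, not done
    assert not harness.divides
    assert org.cpu.copied_count < GENOME_LEN


def test_removing_if_label_keeps_replication_but_slows_it(harness):
    """Without if-label the divide is attempted every loop iteration (extra
    cycles), completing only when copying is done."""
    from digevo.genetics import knockout

    no_f = knockout(build_ancestor(), {OP.IF_LABEL})
    org, ctx = run_until_divide(no_f)
    offspring, gestation = ctx.divides[0]
    assert offspring == no_f  # still a faithful replicator
    assert gestation > 468  # unguarded divide attempts cost cycles


def test_determinism_identical_seed_gives_identical_event_stream():
    def stream():
        ctx = HarnessCtx(copy_mut_prob=5e-3, seed=7)
        org = Organism(build_ancestor())
        events = []
        for _ in range(2000):
            events.extend(vm_step(org, ctx))
        return [(e.kind, e.payload) for e in events]

    assert stream() == stream()


def test_genome_length_conserved_across_generations():
    ctx = HarnessCtx(copy_mut_prob=0.01, seed=3)
    org = Organism(build_ancestor())
    used = 0
    while len(ctx.divides) < 5 and used < 50_000:
        used += execute_cycles(org, 500, ctx)
    assert ctx.divides
    for offspring, _ in ctx.divides:
        assert len(offspring) == GENOME_LEN


def test_serialize_parse_of_vm_outputs_roundtrip():
    genome = build_ancestor()
    assert parse(serialize(genome)) == genome
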