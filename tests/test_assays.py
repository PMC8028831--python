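"""Per-genotype assays: isolation, viability, phenotype, utility, complexity."""

import math
from itertools import combinations_with_replacement

import pytest

from digevo.assays import (
    PROFILE_INPUT_CYCLE,
    ancestor_gestation,
    fitness_assay,
    isolation_assay,
    joint_phenotype_profile,
    marginal_utility,
    phenotype_profile,
    task_complexity,
    viability,
)
from digevo.environment import TASKS, TASK_INDEX
from digevo.genetics import (
    build_ancestor,
    build_dead,
    build_loop2x,
    build_loop4x,
    build_messenger,
)
from digevo.world import BASE_MERIT, RunConfig, World


def test_dead_genome_assays_as_sterile():
    r = isolation_assay(build_dead())
    assert (r.merit, r.gestation, r.platform_fitness) == (BASE_MERIT, math.inf, 0.0)


def test_ancestor_gestation_equals_hand_traced_count():
    assert ancestor_gestation() == 468
    r = isolation_assay(build_ancestor())
    assert r.gestation == 468
    assert r.platform_fitness == pytest.approx(r.merit / 468)


def test_more_h_copies_shorten_gestation():
    g4 = isolation_assay(build_loop4x()).gestation
    g2 = isolation_assay(build_loop2x()).gestation
    ga = isolation_assay(build_ancestor()).gestation
    assert g4 < g2 < ga


def test_viability_counts_fractions():
    anc, dead = build_ancestor(), build_dead()
    assert viability([anc, anc]) == 1.0
    assert viability([dead, dead]) == 0.0
    assert viability([anc, anc, anc, dead]) == 0.75
    with pytest.raises(ValueError):
        viability([])


# ---------------------------------------------------------------------------
# phenotypes

def test_ancestor_performs_not_and_nothing_else():
    p = phenotype_profile(build_ancestor())
    assert p.task_vector == (True,) + (False,) * 8
    assert p.task_counts[0] == 1  # once per gestation
    assert p.class_id == 1


def test_dead_genome_has_the_empty_phenotype():
    p = phenotype_profile(build_dead())
    assert p.task_vector == (False,) * 9
    assert p.class_id == 0


def test_messenger_pair_jointly_performs_nor_that_neither_does_alone():
    msg = build_messenger()
    solo = phenotype_profile(msg)
    assert not solo.task_vector[TASK_INDEX["NOR"]]
    pa, pb = joint_phenotype_profile(msg, msg)
    joint = [a or b for a, b in zip(pa.task_vector, pb.task_vector)]
    assert joint[TASK_INDEX["NOR"]]


def test_profile_inputs_are_5bit_and_echo_safe():
    from digevo.environment import classify_output

    a, b, c = PROFILE_INPUT_CYCLE
    assert all(0 <= v < 32 for v in (a, b, c))
    assert classify_output(0, [a, b]) == set()
    assert classify_output(0, [a, b, c]) == set()
    assert classify_output(c, [a, b, c]) == set()


# ---------------------------------------------------------------------------
# fitness assay and marginal utility

def test_fitness_assay_matches_event_log_recount():
    """The reported births/update equals an independent recount of birth
    events from the assay world's own log."""
    cfg = RunConfig(size=36, updates=150, divide_mut_prob=0.0, rstar=1000.0, seed=9)
    world = World(cfg)
    cells = world.rng.sample(range(36), 30)
    for cell in cells:
        world.seed_organism(build_ancestor(), cell=cell)
    for _ in range(150):
        world.run_update()
    recount = sum(world.log.births[50:]) / 100
    f = fitness_assay(
        build_ancestor(), seed=9, rstar=1000.0, world_size=36, copies=30,
        stabilize=50, measure=100,
    )
    assert f == pytest.approx(recount)


def test_assay_is_deterministic_in_the_seed():
    kw = dict(rstar=1000.0, world_size=36, copies=30, stabilize=30, measure=60)
    f1 = fitness_assay(build_ancestor(), seed=5, **kw)
    f2 = fitness_assay(build_ancestor(), seed=5, **kw)
    assert f1 == f2


def test_assay_stability_across_seeds():
    """Coefficient of variation across seeds stays below 10% (ancestor)."""
    kw = dict(rstar=1000.0, world_size=64, copies=56, stabilize=40, measure=120)
    vals = [fitness_assay(build_ancestor(), seed=s, **kw) for s in (1, 2, 3)]
    mean = sum(vals) / len(vals)
    sd = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
    assert sd / mean < 0.10


def test_marginal_utility_zero_when_process_absent():
    u = marginal_utility(
        build_ancestor(), "messaging", seed=3,
        world_size=36, copies=30, stabilize=30, measure=60, rstar=1000.0,
    )
    assert u.utility == 0.0 and u.defined


def test_marginal_utility_is_one_for_a_lethal_knockout():
    u = marginal_utility(
        build_ancestor(), "copying", seed=3,
        world_size=36, copies=30, stabilize=30, measure=60, rstar=1000.0,
    )
    assert u.fitness > 0
    assert u.fitness_knockout == 0.0
    assert u.utility == 1.0


# ---------------------------------------------------------------------------
# task complexity

def brute_force_min_nands():
    """Independent oracle: breadth-first closure over the actual 5-bit pair
    space (1024 input combinations), not the reduced truth tables."""
    pairs = [(a, b) for a in range(32) for b in range(32)]
    va = tuple(a for a, _ in pairs)
    vb = tuple(b for _, b in pairs)

    def nand(u, v):
        return tuple(~(x & y) & 31 for x, y in zip(u, v))

    targets = {
        "NOT": {tuple(~a & 31 for a in va), tuple(~b & 31 for b in vb)},
        "NAND": {nand(va, vb)},
        "AND": {tuple(a & b for a, b in pairs)},
        "ORN": {tuple((a | ~b) & 31 for a, b in pairs), tuple((~a | b) & 31 for a, b in pairs)},
        "OR": {tuple(a | b for a, b in pairs)},
        "ANDN": {tuple(a & ~b & 31 for a, b in pairs), tuple(~a & b & 31 for a, b in pairs)},
        "NOR": {tuple(~(a | b) & 31 for a, b in pairs)},
        "XOR": {tuple(a ^ b for a, b in pairs)},
        "EQU": {tuple(~(a ^ b) & 31 for a, b in pairs)},
    }
    frontier = {frozenset((va, vb))}
    seen = set(frontier)
    best = {}
    depth = 0
    while len(best) < 9 and depth <= 6:
        for state in frontier:
            for name, truths in targets.items():
                if name not in best and truths & state:
                    best[name] = depth
        depth += 1
        nxt = set()
        for state in frontier:
            vals = list(state)
            for f, g in combinations_with_replacement(vals, 2):
                new = nand(f, g)
                if new not in state:
                    grown = state | {new}
                    if grown not in seen:
                        seen.add(grown)
                        nxt.add(grown)
        frontier = nxt
    return best


def test_task_complexity_matches_brute_force_oracle():
    oracle = brute_force_min_nands()
    for t in TASKS:
        assert task_complexity(t) == oracle[t.name], t.name
    assert task_complexity(TASK_INDEX["NAND"]) == 1
    assert task_complexity(TASK_INDEX["NOT"]) == 1
    assert task_complexity(TASK_INDEX["EQU"]) == 5


def test_task_complexity_monotone_along_reward_groups():
    by_value = {}
    for t in TASKS:
        by_value.setdefault(t.value, []).append(task_complexity(t))
    values = sorted(by_value)
    for lo, hi in zip(values, values[1:]):
        assert max(by_value[lo]) <= min(by_value[hi])
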