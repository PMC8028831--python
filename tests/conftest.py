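"""Shared fixtures: a deterministic VM harness and the archetype genomes."""

from __future__ import annotations

import itertools
import random

import pytest

from digevo.instructions import GENOME_LEN
from digevo.vm import Organism, execute_cycles


class HarnessCtx:
    """Minimal deterministic execution context for VM-level tests.

    Inputs cycle through a fixed script; all side effects are recorded.
    """

    def __init__(self, inputs=(3, 5, 9), copy_mut_prob=0.0, min_copied=GENOME_LEN, seed=0):
        self.rng = random.Random(seed)
        self.copy_mut_prob = copy_mut_prob
        self.min_copied_sites = min_copied
        self._inputs = itertools.cycle(inputs)
        self.outputs: list[int] = []
        self.divides: list[tuple[list[int], int]] = []
        self.sent: list[tuple[int, int]] = []
        self.bcasts: list[tuple[int, int]] = []
        self.random_calls = 0
        self.code_draws = 0

    def random(self):
        self.random_calls += 1
        return self.rng.random()

    def random_code(self):
        self.code_draws += 1
        return self.rng.randrange(32)

    def next_input(self, org):
        return next(self._inputs)

    def output(self, org, value):
        self.outputs.append(value)

    def divide(self, org, offspring):
        self.divides.append((list(offspring), org.last_gestation))

    def send(self, org, v1, v2):
        self.sent.append((v1, v2))

    def bcast(self, org, v1, v2):
        self.bcasts.append((v1, v2))


def run_until_divide(genome, ctx=None, budget=20_000):
    """Execute a genome in the harness until its first divide (or budget)."""
    ctx = ctx or HarnessCtx()
    org = Organism(list(genome))
    used = 0
    while used < budget and not ctx.divides:
        used += execute_cycles(org, 100, ctx)
    return org, ctx


@pytest.fixture
def harness():
    return HarnessCtx()


@pytest.fixture(scope="session")
def ancestor():
    from digevo.genetics import build_ancestor

    return build_ancestor()


@pytest.fixture(scope="session")
def fixtures_by_name():
    from digevo.experiments import make_fixtures

    return {spec.name: spec for spec in make_fixtures()}
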