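"""Shared fixtures: randomized (tree, data, model) instances spanning
state-space sizes, rate-category counts, and data shapes, with optional
ambiguous tips and zero-length branches."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import phylograd as pg
from phylograd.engine import EngineConfig, LikelihoodInstance
from phylograd.seqdata import (
    codon_state_encoder,
    compress_patterns,
    nucleotide_state_map,
)
from phylograd.simulate import random_tree, simulate_alignment


@dataclass
class Instance:
    tree: "pg.Phylogeny"
    patterns: "pg.PatternAlignment"
    Q: "pg.GeneratorMatrix"
    rates: "pg.RateCategories"
    descriptor: dict

    def engine(self, **cfg_kw) -> LikelihoodInstance:
        return LikelihoodInstance(
            self.tree, self.patterns, self.Q, self.rates, EngineConfig(**cfg_kw)
        )


def make_model(S: int, R: int):
    if S == 4:
        Q = pg.gtr_generator([1.0, 2.5, 1.2, 0.8, 3.0, 1.0], [0.35, 0.15, 0.2, 0.3])
    elif S == 61:
        Q = pg.codon_generator(kappa=2.0, omega=0.5)
    else:
        raise ValueError(S)
    rates = pg.single_rate() if R == 1 else pg.discrete_gamma(0.5, R)
    return Q, rates


def make_instance(
    N: int,
    S: int,
    R: int,
    C: int,
    seed: int,
    ambiguous: bool = True,
    zero_branch: bool = True,
) -> Instance:
    """Simulate an instance under the exact engine model, then inject
    ambiguity symbols and a zero-length branch."""
    rng = np.random.default_rng(seed)
    Q, rates = make_model(S, R)
    tree = random_tree(N, rng, mean_branch_length=0.12)
    if zero_branch and N > 2:
        tree.branch_lengths[0] = 0.0
    aln = simulate_alignment(tree, Q, rates, C, rng)
    if ambiguous:
        n_amb = max(1, (N * C) // 20)
        taxa = rng.integers(0, N, size=n_amb)
        cols = rng.integers(0, C, size=n_amb)
        for t, c in zip(taxa, cols):
            if S == 4:
                aln.rows[t][c] = str(rng.choice(["N", "R", "-", "Y"]))
            else:
                cod = aln.rows[t][c]
                aln.rows[t][c] = cod[:2] + "N"
    encoder = nucleotide_state_map() if S == 4 else codon_state_encoder()
    patterns = compress_patterns(aln, encoder, state_count=S)
    return Instance(
        tree=tree,
        patterns=patterns,
        Q=Q,
        rates=rates,
        descriptor={"N": N, "S": S, "R": R, "C": C, "seed": seed},
    )


def suite_grid(ns=(2, 4, 8, 16), ss=(4, 61), rs=(1, 4), cs=(1, 10, 50)):
    """The randomized cross used by the engine-validation suites."""
    seed = 1000
    for N in ns:
        for S in ss:
            for R in rs:
                for C in cs:
                    seed += 1
                    yield (N, S, R, C, seed)


@pytest.fixture(scope="session")
def small_nt_instance() -> Instance:
    return make_instance(N=6, S=4, R=4, C=40, seed=11)


@pytest.fixture(scope="session")
def small_codon_instance() -> Instance:
    return make_instance(N=4, S=61, R=2, C=15, seed=12)


@pytest.fixture(scope="session")
def clean_nt_instance() -> Instance:
    """No ambiguity, no zero branches — for closed-form style checks."""
    return make_instance(N=8, S=4, R=1, C=60, seed=13, ambiguous=False, zero_branch=False)
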