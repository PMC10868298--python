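"""Synthetic data: random trees and CTMC-evolved alignments.

The generator realizes exactly the model the engine evaluates: per column,
a rate category is drawn from its mixture weights, a root state from the
stationary distribution, and child states along each branch from the rows
of exp(gamma_r * b * Q).  One seeded random stream drives a simulation,
consumed in a documented order — all rate categories, then all root states,
then branch transitions column-vectorized in pre-order — so outputs are
exactly reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError
from .models import (
    GeneratorMatrix,
    RateCategories,
    discrete_gamma,
    gtr_generator,
    jc69_generator,
    single_rate,
    transition_probabilities,
)
from .seqdata import Alignment
from .trees import Phylogeny, traversal_schedule

__all__ = [
    "SimulationSpec",
    "random_tree",
    "simulate_alignment",
    "benchmark_fixture",
    "BENCHMARK_PRESETS",
]


@dataclass
class SimulationSpec:
    """Reproducible description of one synthetic dataset."""

    taxon_count: int
    column_count: int
    seed: int
    model: str = "jc69"  # jc69 | gtr | codon
    gamma_shape: float | None = None
    categories: int = 1
    branch_length_mean: float = 0.1
    branch_length_distribution: str = "exponential"

    def validate(self) -> None:
        if self.taxon_count < 2 or self.column_count < 1:
            raise InvalidParameterError("need N >= 2 and C >= 1")


def random_tree(
    n_taxa: int,
    seed_or_rng,
    mean_branch_length: float = 0.1,
    distribution: str = "exponential",
) -> Phylogeny:
    """Random rooted bifurcating tree by sequential coalescence of lineages.

    Branch lengths are i.i.d. from the named distribution (default
    exponential with mean 0.1 expected substitutions).
    """
    if n_taxa < 2:
        raise InvalidParameterError("need at least two taxa")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    N = n_taxa
    M = 2 * N - 1
    parent = np.full(M, -1, dtype=np.int64)
    children = np.full((M, 2), -1, dtype=np.int64)
    active = list(range(N))
    nxt = N
    while len(active) > 1:
        a, b = sorted(rng.choice(len(active), size=2, replace=False))
        nb = active.pop(b)
        na = active.pop(a)
        parent[na] = parent[nb] = nxt
        children[nxt] = (na, nb)
        active.append(nxt)
        nxt += 1
    if distribution == "exponential":
        lengths = rng.exponential(mean_branch_length, size=M)
    elif distribution == "uniform":
        lengths = rng.uniform(0.0, 2 * mean_branch_length, size=M)
    elif distribution == "constant":
        lengths = np.full(M, mean_branch_length)
    else:
        raise InvalidParameterError(f"unknown branch-length distribution {distribution!r}")
    lengths[M - 1] = 0.0
    tree = Phylogeny(
        taxon_names=[f"t{i + 1}" for i in range(N)],
        parent=parent,
        children=children,
        branch_lengths=lengths,
    )
    tree.validate()
    return tree


def simulate_alignment(
    tree: Phylogeny,
    Q: GeneratorMatrix,
    rates: RateCategories,
    n_columns: int,
    seed_or_rng,
) -> Alignment:
    """Evolve ``n_columns`` independent columns down the tree under
    (Q, rates) and emit tip symbols from the generator's state labels."""
    if n_columns < 1:
        raise InvalidParameterError("need at least one column")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    C = n_columns
    S = Q.size
    labels = Q.state_labels or tuple(f"s{i}" for i in range(S))

    cat = rng.choice(rates.count, size=C, p=rates.weights)
    states = np.empty((tree.n_nodes, C), dtype=np.int64)
    states[tree.root] = rng.choice(S, size=C, p=Q.stationary)

    sched = traversal_schedule(tree)
    P = {
        i: transition_probabilities(Q, rates, float(tree.branch_lengths[i])).matrices
        for i in range(tree.n_nodes - 1)
    }
    u_all = rng.random(size=(len(sched.preorder), C))
    for step, (i, k, _) in enumerate(sched.preorder):
        rows = P[i][cat, states[k], :]  # (C, S) transition rows
        cdf = np.cumsum(rows, axis=1)
        states[i] = np.minimum((cdf < u_all[step][:, None]).sum(axis=1), S - 1)

    rows = [[labels[s] for s in states[t]] for t in range(tree.n_taxa)]
    return Alignment(taxon_names=list(tree.taxon_names), rows=rows)


#: Deterministic fixtures with dataset shapes used across the test and
#: scaling suites (names describe the shape, all content is simulated).
BENCHMARK_PRESETS = {
    "small-nt": dict(n_taxa=16, n_columns=100, model="gtr", categories=4, seed=20240117),
    "small-codon": dict(n_taxa=8, n_columns=60, model="codon", categories=2, seed=20240118),
    "tall-tree": dict(n_taxa=512, n_columns=100, model="codon", categories=1, seed=20240119),
}


def benchmark_fixture(preset: str):
    """Build a named deterministic (tree, alignment, model) fixture.

    Presets: ``small-nt`` (N=16, C=100, S=4, R=4 GTR), ``small-codon``
    (N=8, S=61, R=2), ``tall-tree`` (N=512, C=100, S=61 codon, unit branch
    lengths — per-pattern likelihoods near exp(-N log S), far below the
    double-precision floor, so pruning underflows without rescaling).
    """
    if preset not in BENCHMARK_PRESETS:
        raise InvalidParameterError(
            f"unknown preset {preset!r}; choose from {sorted(BENCHMARK_PRESETS)}"
        )
    spec = BENCHMARK_PRESETS[preset]
    rng = np.random.default_rng(spec["seed"])
    if spec["model"] == "gtr":
        Q = gtr_generator(
            exchangeabilities=[1.0, 2.5, 1.2, 0.8, 3.0, 1.0],
            base_frequencies=[0.3, 0.2, 0.2, 0.3],
        )
        rates = discrete_gamma(0.5, spec["categories"])
    elif spec["model"] == "codon":
        from .models import codon_generator

        Q = codon_generator(kappa=2.0, omega=0.5)
        rates = discrete_gamma(1.0, spec["categories"])
    else:
        Q = jc69_generator()
        rates = single_rate() if spec["categories"] == 1 else discrete_gamma(0.5, spec["categories"])
    tree = random_tree(spec["n_taxa"], rng, mean_branch_length=0.1)
    if preset == "tall-tree":
        tree.branch_lengths[: tree.n_nodes - 1] = 1.0
    aln = simulate_alignment(tree, Q, rates, spec["n_columns"], rng)
    return tree, aln, {"generator": Q, "rates": rates, "spec": dict(spec)}
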