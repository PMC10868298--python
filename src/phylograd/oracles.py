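"""Independent, deliberately slow validators for the likelihood engine.

Three routes to the same quantities, none sharing code with the engine's
gradient path:

* the quadratic-time matrix-derivative gradient (rerun pruning once per
  branch with that branch's transition matrix replaced by its derivative),
* central finite differences of the log-likelihood, and
* exhaustive enumeration over internal-node state assignments for small
  trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field

import numpy as np

from .engine import (
    EngineConfig,
    LikelihoodInstance,
    log_likelihood,
    postorder_pass,
    tree_transition_matrices,
)
from .exceptions import InvalidParameterError
from .models import GeneratorMatrix, RateCategories, transition_probabilities
from .seqdata import PatternAlignment, encode_tips
from .trees import Phylogeny, traversal_schedule

__all__ = [
    "OracleReport",
    "gradient_matrix_derivative",
    "gradient_finite_difference",
    "likelihood_exhaustive",
    "gradient_exhaustive",
    "pattern_values_exhaustive",
    "compare_gradients",
]


@dataclass
class OracleReport:
    """Outcome of one engine-versus-oracle comparison."""

    descriptor: dict
    max_abs_deviation: float
    max_rel_deviation: float
    tolerance: float
    passed: bool
    details: dict = _field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "descriptor": self.descriptor,
            "max_abs_deviation": self.max_abs_deviation,
            "max_rel_deviation": self.max_rel_deviation,
            "tolerance": self.tolerance,
            "passed": self.passed,
            **({"details": self.details} if self.details else {}),
        }


def _pattern_likelihoods(
    tree: Phylogeny,
    patterns: PatternAlignment,
    Q: GeneratorMatrix,
    rates: RateCategories,
    derivative_branch: int | None = None,
) -> np.ndarray:
    """Per-pattern (derivative of the) likelihood via plain unscaled pruning."""
    cfg = EngineConfig(scaling="off")
    sched = traversal_schedule(tree)
    tips = encode_tips(patterns)
    mats = tree_transition_matrices(
        tree, Q, rates, cfg, derivative_branch=derivative_branch
    )
    ws = postorder_pass(
        tree, sched, tips, mats, cfg, allow_negative=derivative_branch is not None
    )
    return np.einsum("rcs,s,r->c", ws.post[tree.root], Q.stationary, rates.weights)


def gradient_matrix_derivative(
    tree: Phylogeny,
    patterns: PatternAlignment,
    Q: GeneratorMatrix,
    rates: RateCategories,
) -> np.ndarray:
    """O(N^2) gradient: one full pruning pass per branch with dP/db
    substituted on that branch only."""
    L = _pattern_likelihoods(tree, patterns, Q, rates)
    if np.any(L <= 0):
        raise InvalidParameterError(
            "pattern likelihood underflows without rescaling; instance too "
            "large for the quadratic oracle"
        )
    w = patterns.weights.astype(float)
    grad = np.empty(tree.n_nodes - 1)
    for i in range(tree.n_nodes - 1):
        dL = _pattern_likelihoods(tree, patterns, Q, rates, derivative_branch=i)
        grad[i] = float(np.dot(w, dL / L))
    return grad


def gradient_finite_difference(
    tree: Phylogeny,
    patterns: PatternAlignment,
    Q: GeneratorMatrix,
    rates: RateCategories,
    step: float = 1e-6,
) -> np.ndarray:
    """Finite differences of the log-likelihood per branch: central stencil
    in the interior, second-order one-sided stencil at the b = 0 boundary."""
    if step <= 0:
        raise InvalidParameterError("step must be positive")
    inst = LikelihoodInstance(tree, patterns, Q, rates, EngineConfig(scaling="always"))
    b0 = tree.branch_lengths[: tree.n_nodes - 1].astype(float)
    grad = np.empty(len(b0))
    for i in range(len(b0)):
        b = b0.copy()
        if b0[i] >= step:
            b[i] = b0[i] + step
            up = inst.log_likelihood(b)
            b[i] = b0[i] - step
            dn = inst.log_likelihood(b)
            grad[i] = (up - dn) / (2 * step)
        else:
            # (-3 f(x) + 4 f(x+h) - f(x+2h)) / 2h, O(h^2) at the boundary
            at = inst.log_likelihood(b0)
            b[i] = b0[i] + step
            up1 = inst.log_likelihood(b)
            b[i] = b0[i] + 2 * step
            up2 = inst.log_likelihood(b)
            grad[i] = (-3 * at + 4 * up1 - up2) / (2 * step)
    return grad


def pattern_values_exhaustive(
    tree: Phylogeny,
    patterns: PatternAlignment,
    Q: GeneratorMatrix,
    rates: RateCategories,
    derivative_branch: int | None = None,
    max_assignments: int = 10**6,
) -> np.ndarray:
    """Per-pattern likelihood (or its branch-length derivative) by explicit
    summation over all internal-node state assignments and rate categories.

    With ``derivative_branch`` set, that branch's transition matrices are
    replaced by gamma_r Q exp(gamma_r b Q) inside the enumeration, giving
    dP(Y_c)/db_i with no engine code involved.
    """
    from .models import transition_derivative

    N = tree.n_taxa
    S = Q.size
    n_internal = N - 1
    if S**n_internal > max_assignments:
        raise InvalidParameterError(
            f"{S}^{n_internal} internal-state assignments exceed the "
            f"exhaustive-oracle bound {max_assignments}"
        )
    tips = encode_tips(patterns).indicators  # (N, C, S)
    C = tips.shape[1]
    P = []
    for i in range(tree.n_nodes - 1):
        b = float(tree.branch_lengths[i])
        if derivative_branch is not None and i == derivative_branch:
            P.append(transition_derivative(Q, rates, b).matrices)
        else:
            P.append(transition_probabilities(Q, rates, b).matrices)
    internal_ids = list(range(N, tree.n_nodes))
    root = tree.root

    site = np.zeros((rates.count, C))
    for assign in np.ndindex(*([S] * n_internal)):
        state = dict(zip(internal_ids, assign))
        for r in range(rates.count):
            prob = np.full(C, Q.stationary[state[root]])
            for i in range(tree.n_nodes - 1):
                k = int(tree.parent[i])
                if tree.is_tip(i):
                    # marginalize the tip over its compatibility set
                    prob = prob * (tips[i] @ P[i][r][state[k], :])
                else:
                    prob = prob * P[i][r][state[k], state[i]]
            site[r] += prob
    return rates.weights @ site


def likelihood_exhaustive(
    tree: Phylogeny,
    patterns: PatternAlignment,
    Q: GeneratorMatrix,
    rates: RateCategories,
    max_assignments: int = 10**6,
) -> float:
    """Log-likelihood by exhaustive enumeration (see
    :func:`pattern_values_exhaustive`)."""
    mixture = pattern_values_exhaustive(
        tree, patterns, Q, rates, max_assignments=max_assignments
    )
    if np.any(mixture <= 0):
        raise InvalidParameterError("zero pattern likelihood in exhaustive enumeration")
    return float(np.dot(patterns.weights.astype(float), np.log(mixture)))


def gradient_exhaustive(
    tree: Phylogeny,
    patterns: PatternAlignment,
    Q: GeneratorMatrix,
    rates: RateCategories,
    max_assignments: int = 10**6,
) -> np.ndarray:
    """Per-branch gradient by exhaustive enumeration: d log P(Y_c)/db_i =
    [dP(Y_c)/db_i] / P(Y_c) summed with pattern weights."""
    L = pattern_values_exhaustive(tree, patterns, Q, rates, max_assignments=max_assignments)
    w = patterns.weights.astype(float)
    grad = np.empty(tree.n_nodes - 1)
    for i in range(tree.n_nodes - 1):
        dL = pattern_values_exhaustive(
            tree, patterns, Q, rates, derivative_branch=i, max_assignments=max_assignments
        )
        grad[i] = float(np.dot(w, dL / L))
    return grad


def compare_gradients(
    engine_grad: np.ndarray,
    oracle_grad: np.ndarray,
    tolerance: float,
    descriptor: dict | None = None,
) -> OracleReport:
    """Elementwise comparison with a relative tolerance floored at 1 in the
    denominator (so near-zero entries are compared absolutely)."""
    a = np.asarray(engine_grad, dtype=float)
    b = np.asarray(oracle_grad, dtype=float)
    abs_dev = np.abs(a - b)
    scale = np.maximum(1.0, np.maximum(np.abs(a), np.abs(b)))
    rel_dev = abs_dev / scale
    return OracleReport(
        descriptor=descriptor or {},
        max_abs_deviation=float(abs_dev.max()),
        max_rel_deviation=float(rel_dev.max()),
        tolerance=tolerance,
        passed=bool(rel_dev.max() <= tolerance),
    )
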