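"""Likelihood engine: post-order pruning, pre-order traversal, and the
linear-time gradient of the log-likelihood with respect to all branch
lengths.

Model
-----
Site patterns Y_c arise independently from a CTMC with generator Q running
along the branches of a rooted bifurcating tree, modulated per column by a
rate scalar gamma_r drawn from a finite mixture.  The post-order partial
p_ircs = P(data below node i | state s at i, gamma_r) is computed by
pruning,

    p_k = [P^(r)(b_i) p_i] o [P^(r)(b_j) p_j],

and the pre-order partial q_ircs = P(state s at i, data not below i |
gamma_r) by the reverse recursion starting from q_root = pi,

    q_i = [P^(r)(b_i)]' { q_k o [P^(r)(b_j)] p_j }.

At any node the pattern likelihood is sum_r (p_irc . q_irc) P(gamma_r), and
the derivative of the per-pattern log-likelihood with respect to b_i is the
ratio

    sum_r gamma_r (p_irc' Q' q_irc) P(gamma_r)
    ------------------------------------------ ,
    sum_r         (p_irc' q_irc)   P(gamma_r)

so one post-order and one pre-order pass yield the whole gradient in O(N).

Rescaling
---------
With ``scaling="always"`` each internal node's post-order partials are
divided by M_ic = max over (r, s), one scaler per (node, pattern) shared
across rate categories so the rate mixture stays valid; log-scalers
accumulate per pattern.  Pre-order partials are never rescaled on their own
— they inherit the post-order scalers of the sibling subtrees through the
recursion and the corresponding log sums are tracked per node.  The
gradient ratio is invariant to all scalers (they cancel between numerator
and denominator).

Engine variants
---------------
``reference`` is the plain recursion.  ``batched`` mirrors the many-core
formulation: partials live in contiguous (rate, pattern, state) blocks,
transposed transition matrices are precomputed for all branches before the
pre-order pass, the pre-order update runs as two sequenced stages (sibling
stage, then transposed-matrix stage), the gradient accumulates
state-specific numerator/denominator entries serially over rate categories
before a state reduction, and the state dimension may be zero-padded to a
multiple of 16.  Both variants implement one contract and agree to
round-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidParameterError, InvalidStateError, NumericalError
from .models import (
    GeneratorMatrix,
    RateCategories,
    TransitionMatrixSet,
    pad_matrix_set,
    transition_probabilities,
    transpose_for_preorder,
)
from .seqdata import PatternAlignment, TipEncoding, encode_tips
from .trees import Phylogeny, TraversalSchedule, traversal_schedule

__all__ = [
    "EngineConfig",
    "PartialsWorkspace",
    "GradientResult",
    "tree_transition_matrices",
    "postorder_pass",
    "log_likelihood",
    "preorder_pass",
    "log_likelihood_at_node",
    "branch_gradient",
    "reduce_site_contributions",
    "reduce_branch_set",
    "LikelihoodInstance",
]

_AUTO_THRESHOLD = 1e-100


@dataclass
class EngineConfig:
    """Engine options.

    variant: "reference" or "batched".
    scaling: "off" (raw partials), "always" (rescale every internal node),
        or "auto" (rescale only when a partial's maximum drops below 1e-100).
    pad_states: batched variant only — zero-pad S to the next multiple of 16.
    """

    variant: str = "reference"
    scaling: str = "always"
    pad_states: bool = False

    def validate(self) -> None:
        if self.variant not in ("reference", "batched"):
            raise InvalidParameterError(f"unknown engine variant {self.variant!r}")
        if self.scaling not in ("off", "always", "auto"):
            raise InvalidParameterError(f"unknown scaling mode {self.scaling!r}")
        if self.pad_states and self.variant != "batched":
            raise InvalidParameterError("pad_states applies to the batched variant only")


@dataclass
class PartialsWorkspace:
    """Per-node partial likelihood tables.

    post, pre: (2N-1, R, C, S_pad) arrays of p_irc and q_irc.
    post_logscale: (2N-1, C) accumulated log M_ic below (and at) each node.
    pre_logscale: (2N-1, C) accumulated log-scalers inherited from the
        non-descendant part of the tree through the pre-order recursion.
    """

    post: np.ndarray
    pre: np.ndarray
    post_logscale: np.ndarray
    pre_logscale: np.ndarray
    state_count: int
    post_done: bool = False
    pre_done: bool = False


@dataclass
class GradientResult:
    """Gradient of the log-likelihood wrt every branch length, indexed by
    child node (0 .. 2N-3); optionally the per-pattern contributions."""

    per_branch: np.ndarray
    per_pattern: np.ndarray | None = None


# ---------------------------------------------------------------------------
# matrix preparation
# ---------------------------------------------------------------------------


def tree_transition_matrices(
    tree: Phylogeny,
    Q: GeneratorMatrix,
    rates: RateCategories,
    cfg: EngineConfig | None = None,
    derivative_branch: int | None = None,
) -> list[TransitionMatrixSet]:
    """Transition matrices for all 2N-2 branches (indexed by child node).

    With ``derivative_branch`` set, that branch's matrices are replaced by
    dP/db — the substitution step of the quadratic-time gradient method.
    """
    from .models import transition_derivative  # local to avoid cycle noise

    cfg = cfg or EngineConfig()
    out = []
    for i in range(tree.n_nodes - 1):
        b = float(tree.branch_lengths[i])
        if derivative_branch is not None and i == derivative_branch:
            tms = transition_derivative(Q, rates, b)
        else:
            tms = transition_probabilities(Q, rates, b)
        if cfg.variant == "batched" and cfg.pad_states:
            tms = pad_matrix_set(tms)
        out.append(tms)
    return out


def _padded_width(S: int, cfg: EngineConfig) -> int:
    if cfg.variant == "batched" and cfg.pad_states:
        return -(-S // 16) * 16
    return S


# ---------------------------------------------------------------------------
# post-order pass
# ---------------------------------------------------------------------------


def postorder_pass(
    tree: Phylogeny,
    schedule: TraversalSchedule,
    tips: TipEncoding,
    matrices: list[TransitionMatrixSet],
    cfg: EngineConfig | None = None,
    allow_negative: bool = False,
) -> PartialsWorkspace:
    """Felsenstein pruning with optional per-(node, pattern) rescaling.

    ``allow_negative`` admits signed "partials", needed when a transition
    matrix has been replaced by its branch-length derivative (the
    quadratic-time gradient oracle); ordinary likelihood passes reject
    negative partials as numerical failures.
    """
    cfg = cfg or EngineConfig()
    cfg.validate()
    N = tree.n_taxa
    M = tree.n_nodes
    R = matrices[0].matrices.shape[0]
    C = tips.indicators.shape[1]
    S = tips.indicators.shape[2]
    Sp = _padded_width(S, cfg)
    if len(matrices) != M - 1:
        raise InvalidParameterError("need one transition-matrix set per branch")

    post = np.zeros((M, R, C, Sp))
    post[:N, :, :, :S] = tips.indicators[:, None, :, :]
    post_logscale = np.zeros((M, C))

    # transposed-in-last-axes views: (P p)_s = sum_t P_st p_t  ==  p @ P'
    PT = [m.matrices.swapaxes(-1, -2) for m in matrices]

    for k, i, j in schedule.postorder:
        pk = (post[i] @ PT[i]) * (post[j] @ PT[j])
        acc = post_logscale[i] + post_logscale[j]
        if cfg.scaling != "off":
            m = pk.max(axis=(0, 2))  # shared across rate categories
            if cfg.scaling == "always":
                do = m > 0
            else:
                do = (m > 0) & (m < _AUTO_THRESHOLD)
            if np.any(do):
                scale = np.where(do, m, 1.0)
                pk = pk / scale[None, :, None]
                acc = acc + np.where(do, np.log(scale), 0.0)
        invalid = ~np.isfinite(pk)
        if not allow_negative:
            invalid |= pk < 0
        if np.any(invalid):
            bad = np.argwhere(invalid)
            raise NumericalError(
                f"invalid post-order partial at node {k}, pattern {int(bad[0][1])}",
                node=k,
                patterns=sorted({int(b[1]) for b in bad}),
            )
        post[k] = pk
        post_logscale[k] = acc

    return PartialsWorkspace(
        post=post,
        pre=np.zeros_like(post),
        post_logscale=post_logscale,
        pre_logscale=np.zeros((M, C)),
        state_count=S,
        post_done=True,
    )


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------


def _pattern_log_likelihoods(
    ws: PartialsWorkspace, root: int, root_prior: np.ndarray, rates: RateCategories
) -> np.ndarray:
    S = ws.state_count
    site = np.einsum(
        "rcs,s,r->c", ws.post[root][:, :, :S], root_prior, rates.weights
    )
    bad = np.nonzero(site <= 0.0)[0]
    if bad.size:
        raise NumericalError(
            "zero pattern likelihood (underflow or impossible data) at "
            f"pattern(s) {bad.tolist()[:10]}",
            patterns=bad.tolist(),
        )
    return np.log(site) + ws.post_logscale[root]


def log_likelihood(
    ws: PartialsWorkspace,
    root_prior: np.ndarray,
    rates: RateCategories,
    weights: np.ndarray,
    root: int | None = None,
) -> float:
    """Weighted log-likelihood over site patterns from completed post-order
    partials (scaler corrections included)."""
    if not ws.post_done:
        raise InvalidStateError("post-order pass has not been run")
    if root is None:
        root = ws.post.shape[0] - 1
    per_pattern = _pattern_log_likelihoods(ws, root, np.asarray(root_prior), rates)
    return float(np.dot(np.asarray(weights, dtype=float), per_pattern))


# ---------------------------------------------------------------------------
# pre-order pass
# ---------------------------------------------------------------------------


def preorder_pass(
    tree: Phylogeny,
    schedule: TraversalSchedule,
    ws: PartialsWorkspace,
    matrices: list[TransitionMatrixSet],
    root_prior: np.ndarray,
    cfg: EngineConfig | None = None,
    transposed: list[TransitionMatrixSet] | None = None,
) -> PartialsWorkspace:
    """Pre-order recursion computing q_irc at every non-root node (tips
    included, densely).

    The batched variant consumes precomputed transposed matrices (all
    branches transposed up front) and runs the update as two sequenced
    stages; the reference variant transposes on the fly.
    """
    cfg = cfg or EngineConfig()
    cfg.validate()
    if not ws.post_done:
        raise InvalidStateError("pre-order pass requires completed post-order partials")
    root = tree.root
    S = ws.state_count
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (S,):
        raise InvalidParameterError("root prior has wrong length")

    ws.pre[root][:, :, :S] = pi[None, None, :]
    ws.pre[root][:, :, S:] = 0.0
    ws.pre_logscale[root] = 0.0

    batched = cfg.variant == "batched"
    if batched and transposed is None:
        transposed = [transpose_for_preorder(m) for m in matrices]
    PT_sib = [m.matrices.swapaxes(-1, -2) for m in matrices]

    for i, k, j in schedule.preorder:
        # stage 1: sibling contribution and elementwise product with q_k
        sib = ws.post[j] @ PT_sib[j]
        qt = ws.pre[k] * sib
        # stage 2: multiply by the transposed branch matrix
        if batched:
            ws.pre[i] = np.einsum("rst,rct->rcs", transposed[i].matrices, qt)
        else:
            ws.pre[i] = qt @ matrices[i].matrices
        ws.pre_logscale[i] = ws.pre_logscale[k] + ws.post_logscale[j]
    if not np.all(np.isfinite(ws.pre)):
        raise NumericalError("non-finite pre-order partial (overflow)")
    ws.pre_done = True
    return ws


def log_likelihood_at_node(
    ws: PartialsWorkspace,
    node: int,
    rates: RateCategories,
    weights: np.ndarray,
) -> float:
    """Log-likelihood evaluated from the (p, q) pair at any single node;
    equals the root evaluation for every node."""
    if not ws.pre_done:
        raise InvalidStateError("requires completed pre-order pass")
    S = ws.state_count
    site = np.einsum(
        "rcs,rcs,r->c", ws.post[node][:, :, :S], ws.pre[node][:, :, :S], rates.weights
    )
    bad = np.nonzero(site <= 0.0)[0]
    if bad.size:
        raise NumericalError(
            f"zero pattern likelihood at node {node}, pattern(s) {bad.tolist()[:10]}",
            patterns=bad.tolist(),
            node=node,
        )
    logs = np.log(site) + ws.post_logscale[node] + ws.pre_logscale[node]
    return float(np.dot(np.asarray(weights, dtype=float), logs))


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------


def branch_gradient(
    ws: PartialsWorkspace,
    tree: Phylogeny,
    Q: GeneratorMatrix,
    rates: RateCategories,
    weights: np.ndarray,
    cfg: EngineConfig | None = None,
    keep_per_pattern: bool = False,
    category_generators: list[np.ndarray] | None = None,
) -> GradientResult:
    """Gradient of the log-likelihood wrt all 2N-2 branch lengths.

    Default model ties the category generator to gamma_r * Q, with the
    gamma_r factored into the numerator weights.  ``category_generators``
    supplies arbitrary per-category Q^(r) instead (the gamma factor is then
    omitted).  The result is identical whether or not rescaling was active:
    the shared scalers cancel in the numerator/denominator ratio.
    """
    cfg = cfg or EngineConfig()
    if not ws.pre_done:
        raise InvalidStateError("gradient requires completed pre-order pass")
    S = ws.state_count
    M = ws.post.shape[0]
    C = ws.post.shape[2]
    w = np.asarray(weights, dtype=float)

    if category_generators is not None:
        Qr = [np.asarray(q) for q in category_generators]
        num_w = rates.weights
    else:
        Qr = [Q.entries] * rates.count
        num_w = rates.weights * rates.rates

    per_pattern = np.empty((M - 1, C))
    for i in range(M - 1):
        p = ws.post[i][:, :, :S]
        q = ws.pre[i][:, :, :S]
        if cfg.variant == "batched":
            # rate-serial accumulation of state-specific entries, then a
            # state reduction (the many-core gradient kernel structure)
            phi = np.zeros((C, S))
            omega = np.zeros((C, S))
            for r in range(rates.count):
                omega += p[r] * q[r] * rates.weights[r]
                delta = q[r] @ Qr[r]  # (Q' q)_s = sum_t Q_ts q_t
                phi += p[r] * delta * num_w[r]
            num = phi.sum(axis=1)
            den = omega.sum(axis=1)
        else:
            den = np.einsum("rcs,rcs,r->c", p, q, rates.weights)
            qQ = np.stack([q[r] @ Qr[r] for r in range(rates.count)])
            num = np.einsum("rcs,rcs,r->c", p, qQ, num_w)
        bad = np.nonzero(den == 0.0)[0]
        if bad.size:
            raise NumericalError(
                f"zero gradient denominator at branch {i}, pattern(s) "
                f"{bad.tolist()[:10]}",
                patterns=bad.tolist(),
                node=i,
            )
        per_pattern[i] = num / den

    per_branch = reduce_site_contributions(per_pattern, w)
    return GradientResult(
        per_branch=per_branch, per_pattern=per_pattern if keep_per_pattern else None
    )


def reduce_site_contributions(per_pattern: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of per-pattern contributions over patterns, in fixed
    ascending pattern order (bit-reproducible for a given variant)."""
    pp = np.asarray(per_pattern, dtype=float)
    w = np.asarray(weights, dtype=float)
    out = np.zeros(pp.shape[0])
    for c in range(pp.shape[1]):
        out += w[c] * pp[:, c]
    return out


def reduce_branch_set(grad: GradientResult, branch_sets) -> np.ndarray:
    """Sum gradient entries over disjoint sets of branch ids.

    Used e.g. to report a single derivative for all branches sharing a
    clock-style parameter, or to sum the two root-child entries under the
    unrooted convention.
    """
    seen: set[int] = set()
    out = np.zeros(len(branch_sets))
    for s, ids in enumerate(branch_sets):
        ids = list(ids)
        if seen & set(ids):
            raise InvalidParameterError("branch sets must be disjoint")
        if any(i < 0 or i >= len(grad.per_branch) for i in ids):
            raise InvalidParameterError("branch id out of range")
        seen |= set(ids)
        out[s] = grad.per_branch[ids].sum()
    return out


# ---------------------------------------------------------------------------
# convenience facade
# ---------------------------------------------------------------------------


class LikelihoodInstance:
    """One (tree, data, model) problem with cached schedule and encodings.

    Methods accept an optional replacement branch-length vector so callers
    (optimizers, samplers, finite differences) can re-evaluate cheaply.
    """

    def __init__(
        self,
        tree: Phylogeny,
        patterns: PatternAlignment,
        Q: GeneratorMatrix,
        rates: RateCategories,
        cfg: EngineConfig | None = None,
        root_prior: np.ndarray | None = None,
    ):
        if patterns.state_count != Q.size:
            raise InvalidParameterError(
                f"pattern state count {patterns.state_count} != model size {Q.size}"
            )
        if list(patterns.taxon_names) != list(tree.taxon_names):
            order = {n: i for i, n in enumerate(patterns.taxon_names)}
            missing = [n for n in tree.taxon_names if n not in order]
            if missing:
                raise InvalidParameterError(f"taxa missing from alignment: {missing[:5]}")
            perm = [order[n] for n in tree.taxon_names]
            patterns = PatternAlignment(
                taxon_names=list(tree.taxon_names),
                tip_states=[patterns.tip_states[i] for i in perm],
                weights=patterns.weights,
                state_count=patterns.state_count,
            )
        self.tree = tree
        self.patterns = patterns
        self.Q = Q
        self.rates = rates
        self.cfg = cfg or EngineConfig()
        self.cfg.validate()
        self.root_prior = (
            np.asarray(root_prior, dtype=float) if root_prior is not None else Q.stationary
        )
        self.schedule = traversal_schedule(tree)
        self.tips = encode_tips(patterns)
        self.weights = patterns.weights.astype(float)

    @property
    def n_branches(self) -> int:
        return self.tree.n_nodes - 1

    def _with_lengths(self, branch_lengths) -> Phylogeny:
        if branch_lengths is None:
            return self.tree
        b = np.asarray(branch_lengths, dtype=float)
        if b.shape != (self.n_branches,):
            raise InvalidParameterError("branch-length vector has wrong length")
        lengths = self.tree.branch_lengths.copy()
        lengths[: self.n_branches] = b
        return Phylogeny(
            taxon_names=self.tree.taxon_names,
            parent=self.tree.parent,
            children=self.tree.children,
            branch_lengths=lengths,
        )

    def workspace(self, branch_lengths=None, with_preorder=False) -> PartialsWorkspace:
        tree = self._with_lengths(branch_lengths)
        mats = tree_transition_matrices(tree, self.Q, self.rates, self.cfg)
        ws = postorder_pass(tree, self.schedule, self.tips, mats, self.cfg)
        if with_preorder:
            transposed = None
            if self.cfg.variant == "batched":
                transposed = [transpose_for_preorder(m) for m in mats]
            preorder_pass(
                tree, self.schedule, ws, mats, self.root_prior, self.cfg, transposed
            )
        return ws

    def log_likelihood(self, branch_lengths=None) -> float:
        ws = self.workspace(branch_lengths)
        return log_likelihood(ws, self.root_prior, self.rates, self.weights)

    def log_likelihood_and_gradient(
        self, branch_lengths=None, keep_per_pattern=False
    ) -> tuple[float, GradientResult]:
        ws = self.workspace(branch_lengths, with_preorder=True)
        ll = log_likelihood(ws, self.root_prior, self.rates, self.weights)
        grad = branch_gradient(
            ws,
            self.tree,
            self.Q,
            self.rates,
            self.weights,
            self.cfg,
            keep_per_pattern=keep_per_pattern,
        )
        return ll, grad
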