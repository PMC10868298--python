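"""Engine correctness: pruning, pre-order recursion, any-node likelihood,
rescaling, and the linear-time gradient against independent oracles."""

import math

import numpy as np
import pytest
import sympy

import phylograd as pg
from phylograd.engine import (
    EngineConfig,
    LikelihoodInstance,
    branch_gradient,
    log_likelihood,
    log_likelihood_at_node,
    postorder_pass,
    preorder_pass,
    reduce_branch_set,
    reduce_site_contributions,
    tree_transition_matrices,
)
from phylograd.exceptions import InvalidParameterError, InvalidStateError
from phylograd.models import single_rate, transition_probabilities
from phylograd.oracles import (
    gradient_finite_difference,
    gradient_matrix_derivative,
    likelihood_exhaustive,
)
from phylograd.seqdata import Alignment, compress_patterns, encode_tips, nucleotide_state_map
from phylograd.trees import traversal_schedule

from conftest import Instance, make_instance


def all_ambiguous_instance(N=5, C=3, R=2, seed=0):
    aln = Alignment([f"t{i+1}" for i in range(N)], [["N"] * C for _ in range(N)])
    pa = compress_patterns(aln, nucleotide_state_map(), state_count=4)
    from phylograd.simulate import random_tree

    tree = random_tree(N, np.random.default_rng(seed))
    Q, rates = pg.jc69_generator(), (pg.discrete_gamma(0.5, R) if R > 1 else single_rate())
    return Instance(tree, pa, Q, rates, {})


class TestPostorder:
    def test_tip_partials_are_indicators(self, small_nt_instance):
        ws = small_nt_instance.engine().workspace()
        tips = encode_tips(small_nt_instance.patterns).indicators
        for t in range(small_nt_instance.tree.n_taxa):
            for r in range(small_nt_instance.rates.count):
                assert np.array_equal(ws.post[t, r], tips[t])

    def test_zero_child_branches_give_elementwise_product(self):
        tree = pg.parse_newick("((A:0.0,B:0.0):0.1,C:0.2);")
        aln = Alignment(["A", "B", "C"], [list("AR"), list("GN"), list("TT")])
        pa = compress_patterns(aln, nucleotide_state_map(), state_count=4)
        tips = encode_tips(pa)
        sched = traversal_schedule(tree)
        mats = tree_transition_matrices(tree, pg.jc69_generator(), single_rate())
        ws = postorder_pass(tree, sched, tips, mats, EngineConfig(scaling="off"))
        # internal node 3 is the cherry parent of tips A(0), B(1)
        assert np.allclose(ws.post[3], tips.indicators[0] * tips.indicators[1], atol=1e-15)

    def test_root_likelihood_matches_exhaustive_enumeration(self, small_codon_instance):
        inst = make_instance(N=4, S=4, R=2, C=8, seed=77)
        ll = inst.engine(scaling="off").log_likelihood()
        assert ll == pytest.approx(
            likelihood_exhaustive(inst.tree, inst.patterns, inst.Q, inst.rates), abs=1e-10
        )


class TestLogLikelihood:
    def test_all_ambiguous_data_has_zero_log_likelihood(self):
        # every pattern marginalizes to probability 1 (up to the row-sum
        # round-off of the matrix exponential)
        inst = all_ambiguous_instance()
        for scaling in ("off", "always"):
            assert inst.engine(scaling=scaling).log_likelihood() == pytest.approx(
                0.0, abs=1e-12
            )

    def test_two_taxon_jc69_closed_form(self):
        b = 0.37
        tree = pg.parse_newick(f"(A:{b},B:0.0);")
        aln = Alignment(["A", "B"], [list("AC"), list("AG")])  # one match, one mismatch
        pa = compress_patterns(aln, nucleotide_state_map(), state_count=4)
        ll = pg.LikelihoodInstance(tree, pa, pg.jc69_generator(), single_rate()).log_likelihood()
        e = math.exp(-4.0 * b / 3.0)
        match = 0.25 * (0.25 + 0.75 * e)
        mismatch = 0.25 * (0.25 - 0.25 * e)
        assert ll == pytest.approx(math.log(match) + math.log(mismatch), abs=1e-12)

    def test_scaling_off_vs_always_identical(self, small_nt_instance):
        ll_off = small_nt_instance.engine(scaling="off").log_likelihood()
        ll_on = small_nt_instance.engine(scaling="always").log_likelihood()
        assert ll_on == pytest.approx(ll_off, abs=1e-10)

    def test_auto_scaling_matches(self, small_nt_instance):
        ll_auto = small_nt_instance.engine(scaling="auto").log_likelihood()
        ll_on = small_nt_instance.engine(scaling="always").log_likelihood()
        assert ll_auto == pytest.approx(ll_on, abs=1e-10)


def brute_force_preorder(tree, patterns, Q, rates, node, r):
    """q_{node,r,c,s} = P(Y_node = s, tip data not below node | gamma_r)
    by exhaustive enumeration over unconstrained node states."""
    tips = encode_tips(patterns).indicators
    C, S = tips.shape[1], Q.size
    P = {
        i: transition_probabilities(Q, rates, float(tree.branch_lengths[i])).matrices[r]
        for i in range(tree.n_nodes - 1)
    }
    # nodes inside the subtree of `node` contribute nothing (their data are
    # "below"); enumerate states of all other nodes plus `node` itself
    below = set()
    stack = [node]
    while stack:
        u = stack.pop()
        below.add(u)
        if not tree.is_tip(u):
            stack.extend(tree.children[u])
    outside = [u for u in range(tree.n_nodes) if u not in below and not tree.is_tip(u)]
    out = np.zeros((C, S))
    for s in range(S):
        for assign in np.ndindex(*([S] * len(outside))):
            state = dict(zip(outside, assign))
            state[node] = s
            prob = np.ones(C) * Q.stationary[state[tree.root]]
            for u in range(tree.n_nodes - 1):
                if u in below and u != node:  # branch strictly below `node`
                    continue
                k = int(tree.parent[u])
                if u == node:
                    prob = prob * P[u][state[k], s]
                elif tree.is_tip(u):
                    prob = prob * (tips[u] @ P[u][state[k], :])
                else:
                    prob = prob * P[u][state[k], state[u]]
            out[:, s] += prob
    if node == tree.root:
        out[:, :] = Q.stationary[None, :]
    return out


class TestPreorder:
    def test_root_preorder_partial_is_prior(self, small_nt_instance):
        ws = small_nt_instance.engine().workspace(with_preorder=True)
        root = small_nt_instance.tree.root
        pi = small_nt_instance.Q.stationary
        assert np.allclose(ws.pre[root], pi[None, None, :], atol=1e-15)

    def test_zero_branches_with_ambiguous_sibling_copy_parent(self):
        tree = pg.parse_newick("((A:0.0,B:0.0):0.1,C:0.2);")
        aln = Alignment(["A", "B", "C"], [list("A"), list("N"), list("T")])
        pa = compress_patterns(aln, nucleotide_state_map(), state_count=4)
        inst = pg.LikelihoodInstance(tree, pa, pg.jc69_generator(), single_rate())
        ws = inst.workspace(with_preorder=True)
        # tip A: b_A = b_B = 0 and sibling B all-ones => q_A == q_parent
        assert np.allclose(ws.pre[0], ws.pre[3], atol=1e-15)

    def test_preorder_requires_postorder(self, small_nt_instance):
        inst = small_nt_instance.engine()
        ws = inst.workspace()
        ws.post_done = False
        with pytest.raises(InvalidStateError):
            preorder_pass(
                inst.tree,
                inst.schedule,
                ws,
                tree_transition_matrices(inst.tree, inst.Q, inst.rates),
                inst.root_prior,
            )

    def test_matches_exhaustive_enumeration_at_every_node(self):
        inst = make_instance(N=5, S=4, R=2, C=4, seed=21)
        ws = inst.engine(scaling="off").workspace(with_preorder=True)
        for node in range(inst.tree.n_nodes):
            for r in range(inst.rates.count):
                oracle = brute_force_preorder(
                    inst.tree, inst.patterns, inst.Q, inst.rates, node, r
                )
                assert np.allclose(ws.pre[node, r], oracle, atol=1e-12), f"node {node}"


class TestAnyNodeLikelihood:
    @pytest.mark.parametrize("scaling", ["off", "always"])
    def test_every_node_matches_root_evaluation(self, scaling):
        inst = make_instance(N=6, S=4, R=4, C=20, seed=31)
        eng = inst.engine(scaling=scaling)
        ws = eng.workspace(with_preorder=True)
        ll = log_likelihood(ws, eng.root_prior, inst.rates, eng.weights)
        for node in range(inst.tree.n_nodes):
            at = log_likelihood_at_node(ws, node, inst.rates, eng.weights)
            assert at == pytest.approx(ll, abs=1e-10), f"node {node}"

    def test_tip_evaluation_reduces_to_weighted_preorder_entry(self):
        inst = make_instance(N=4, S=4, R=2, C=6, seed=32, ambiguous=False)
        eng = inst.engine()
        ws = eng.workspace(with_preorder=True)
        tip = 0
        states = [inst.patterns.tip_states[tip][c] for c in range(inst.patterns.pattern_count)]
        manual = sum(
            w
            * (
                math.log(
                    sum(
                        inst.rates.weights[r] * ws.pre[tip, r, c, states[c]]
                        for r in range(inst.rates.count)
                    )
                )
                + ws.post_logscale[tip, c]
                + ws.pre_logscale[tip, c]
            )
            for c, w in enumerate(eng.weights)
        )
        assert manual == pytest.approx(
            log_likelihood(ws, eng.root_prior, inst.rates, eng.weights), abs=1e-10
        )


class TestBranchGradient:
    def test_all_ambiguous_gradient_is_exactly_zero(self):
        inst = all_ambiguous_instance()
        _, grad = inst.engine().log_likelihood_and_gradient()
        assert np.allclose(grad.per_branch, 0.0, atol=1e-12)

    def test_two_taxon_jc69_symbolic_derivative(self):
        bsym = sympy.Symbol("b", positive=True)
        site = sympy.Rational(1, 16) + sympy.Rational(3, 16) * sympy.exp(-4 * bsym / 3)
        dlog = sympy.diff(sympy.log(site), bsym)
        b = 0.42
        tree = pg.parse_newick(f"(A:{b},B:0.0);")
        aln = Alignment(["A", "B"], [["C"], ["C"]])
        pa = compress_patterns(aln, nucleotide_state_map(), state_count=4)
        _, grad = pg.LikelihoodInstance(
            tree, pa, pg.jc69_generator(), single_rate()
        ).log_likelihood_and_gradient()
        expected = float(dlog.subs(bsym, b))
        assert grad.per_branch[0] == pytest.approx(expected, abs=1e-10)
        assert grad.per_branch[1] == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("N,S,R", [(4, 4, 1), (8, 4, 4), (16, 4, 4), (4, 61, 2)])
    def test_agrees_with_dual_oracles(self, N, S, R):
        inst = make_instance(N=N, S=S, R=R, C=12, seed=40 + N + S + R)
        _, grad = inst.engine().log_likelihood_and_gradient()
        md = gradient_matrix_derivative(inst.tree, inst.patterns, inst.Q, inst.rates)
        fd = gradient_finite_difference(inst.tree, inst.patterns, inst.Q, inst.rates)
        scale = np.maximum(1.0, np.abs(md))
        assert np.all(np.abs(grad.per_branch - md) / scale < 1e-8)
        assert np.all(np.abs(grad.per_branch - fd) / scale < 1e-5)

    def test_scaling_on_off_gradients_agree(self, small_nt_instance):
        _, g_off = small_nt_instance.engine(scaling="off").log_likelihood_and_gradient()
        _, g_on = small_nt_instance.engine(scaling="always").log_likelihood_and_gradient()
        assert np.allclose(g_on.per_branch, g_off.per_branch, atol=1e-10)

    def test_generalized_per_category_generators_match_tied_default(self):
        inst = make_instance(N=6, S=4, R=3, C=10, seed=55)
        eng = inst.engine()
        ws = eng.workspace(with_preorder=True)
        tied = branch_gradient(ws, inst.tree, inst.Q, inst.rates, eng.weights, eng.cfg)
        general = branch_gradient(
            ws,
            inst.tree,
            inst.Q,
            inst.rates,
            eng.weights,
            eng.cfg,
            category_generators=[g * inst.Q.entries for g in inst.rates.rates],
        )
        assert np.allclose(tied.per_branch, general.per_branch, atol=1e-12)

    def test_per_pattern_contributions_reduce_to_per_branch(self):
        inst = make_instance(N=5, S=4, R=2, C=15, seed=56)
        _, grad = inst.engine().log_likelihood_and_gradient(keep_per_pattern=True)
        recon = grad.per_pattern @ inst.patterns.weights.astype(float)
        assert np.allclose(recon, grad.per_branch, atol=1e-10)

    def test_gradient_requires_preorder(self, small_nt_instance):
        eng = small_nt_instance.engine()
        ws = eng.workspace(with_preorder=False)
        with pytest.raises(InvalidStateError):
            branch_gradient(ws, eng.tree, eng.Q, eng.rates, eng.weights, eng.cfg)


class TestReductions:
    def test_site_reduction_identity_linearity_and_fsum_oracle(self):
        rng = np.random.default_rng(8)
        table = rng.normal(size=(6, 40)) * 10.0 ** rng.integers(-3, 4, size=(6, 40))
        w = rng.integers(1, 9, size=40).astype(float)
        red = reduce_site_contributions(table, w)
        assert np.allclose(
            reduce_site_contributions(table[:, :1], np.array([1.0])), table[:, 0]
        )
        assert np.allclose(reduce_site_contributions(table, 2 * w), 2 * red, atol=1e-12)
        oracle = np.array(
            [math.fsum(w[c] * table[i, c] for c in range(40)) for i in range(6)]
        )
        assert np.all(np.abs(red - oracle) <= 1e-12 * np.maximum(1.0, np.abs(oracle)))

    def test_branch_set_reduction(self):
        grad = pg.GradientResult(per_branch=np.array([1.0, -2.0, 3.5, 0.25]))
        singles = reduce_branch_set(grad, [[0], [1], [2], [3]])
        assert np.allclose(singles, grad.per_branch)
        total = reduce_branch_set(grad, [[0, 1, 2, 3]])
        assert total[0] == pytest.approx(grad.per_branch.sum(), abs=1e-12)
        two = reduce_branch_set(grad, [[0, 2], [1, 3]])
        assert two.sum() == pytest.approx(grad.per_branch.sum(), abs=1e-12)
        with pytest.raises(InvalidParameterError):
            reduce_branch_set(grad, [[0, 1], [1, 2]])


class TestEngineEquivalence:
    @pytest.mark.parametrize("N,S,R,C", [(6, 4, 4, 20), (4, 61, 2, 8), (2, 4, 1, 5)])
    def test_reference_batched_padded_agree(self, N, S, R, C):
        inst = make_instance(N=N, S=S, R=R, C=C, seed=60 + N + S)
        ll_ref, g_ref = inst.engine(variant="reference").log_likelihood_and_gradient()
        ll_bat, g_bat = inst.engine(variant="batched").log_likelihood_and_gradient()
        ll_pad, g_pad = inst.engine(
            variant="batched", pad_states=True
        ).log_likelihood_and_gradient()
        for ll, g in [(ll_bat, g_bat), (ll_pad, g_pad)]:
            assert np.isclose(ll, ll_ref, rtol=1e-12, atol=1e-12)
            assert np.allclose(g.per_branch, g_ref.per_branch, rtol=1e-12, atol=1e-12)

    def test_degenerate_shapes_single_column_and_two_taxa(self):
        inst = make_instance(N=2, S=4, R=4, C=1, seed=70, zero_branch=False)
        ll, grad = inst.engine().log_likelihood_and_gradient()
        assert np.isfinite(ll) and grad.per_branch.shape == (2,)
        fd = gradient_finite_difference(inst.tree, inst.patterns, inst.Q, inst.rates)
        assert np.allclose(grad.per_branch, fd, atol=1e-5)
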