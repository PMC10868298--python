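# Methods

## Model

Alignment columns are i.i.d. draws from a CTMC acting along a rooted
bifurcating tree with `N` tips, `N−2` internal nodes and a root; the
`2N−2` branch lengths are indexed by child node and measured in expected
substitutions per site. An `S×S` generator `Q` with stationary
distribution `π` defines the process; among-site rate variation enters as
a finite mixture of rate scalars `γ_r` (discrete gamma by default), so
branch `i` under category `r` carries `P⁽ʳ⁾(bᵢ) = exp(γ_r bᵢ Q)`. The root
prior defaults to `π`. Unrooted likelihoods are the special case with one
root-child branch set to zero; zero-length branches are legal everywhere.

Supported generators:

* **GTR** (and JC69/HKY as parameter choices): `Q_st = r_st π_t`,
  reversible, six exchangeabilities ordered (AC, AG, AT, CG, CT, GT).
* **Codon** models: states are the sense codons of a genetic code
  (universal: 61; vertebrate mitochondrial: 60 — the state count is always
  derived from the code table), ordered lexicographically over (T, C, A, G).
  Rates between codons differing at exactly one position are
  `π_target · κ^[transition] · ω^[nonsynonymous]`; multi-position changes
  are instantaneous-rate zero. This is the target-frequency (GY-style)
  parameterization; codon frequencies are user-supplied or equal, with no
  preference between F61/F3×4-style estimates — they are inputs here.
* **Markov-modulated** compositions: `K` equally sized components on the
  block diagonal with `switching[a,b]·I` off-diagonal blocks (two codon
  components give `S = 122`). The composite is normalized to mean rate one
  under its own stationary distribution so branch lengths stay in
  expected-substitution units; it is generally non-reversible.

All generators are (optionally) normalized to `−Σ_s π_s Q_ss = 1`.

## Rate discretization

`discrete_gamma(shape, R)` uses `R` equal-weight categories whose rates are
the means of gamma(shape, shape) over equal-probability quantile bands
(computed from the regularized incomplete gamma with shape+1), then
renormalized to mean exactly one. Category means (rather than medians)
preserve the mixture mean that the likelihood sums over. `R = 1` is the
exact no-heterogeneity case. The general engine interface also accepts
arbitrary per-category generators `Q⁽ʳ⁾`; the default ties
`Q⁽ʳ⁾ = γ_r Q`, in which case the `γ_r` appears as an explicit factor in
the gradient numerator, while user-supplied `Q⁽ʳ⁾` are applied directly
without that factor.

## Matrix exponentials

Reversible generators use the symmetric eigendecomposition of
`diag(√π) Q diag(√π)⁻¹`, computed once per generator and reused for every
(category, branch-length) pair — the dominant cost for `S = 61` becomes two
`S×S` matrix products per matrix. Non-reversible generators (the
Markov-modulated composition) fall back to scipy's scaling-and-squaring
`expm`. Round-off negatives from the eigen path (≳ −1e−10 would be an
error) are clipped to zero. Branch-length derivatives are
`γ_r Q exp(γ_r b Q)` on the same decomposition.

## Engine

One post-order pass (pruning) and one pre-order pass produce, for every
node, the pair `(p_irc, q_irc)` from which the likelihood can be read at
any node and the full branch-length gradient follows as weighted inner
products — `O(N)` total, versus `O(N²)` for per-branch matrix-derivative
pruning. Summation order in all reductions is fixed (ascending pattern
index), so repeated runs of a given variant are bit-identical.

**Rescaling.** With `scaling="always"` every internal node's post-order
partials are divided by `M_ic = max_{r,s} p_ircs` — one scaler per
(node, pattern), shared across rate categories so the rate mixture remains
valid — and `log M` accumulates per pattern. `auto` rescales only when a
partial's maximum drops below 1e−100; `off` disables rescaling and raises
a `NumericalError` naming the offending patterns if any pattern likelihood
reaches exact zero. Pre-order partials are never rescaled independently:
they inherit the post-order scalers of the sibling subtrees through the
recursion (tracked per node), the root prior bounds their growth, and
overflow raises. The gradient ratio cancels all scalers, so gradients with
rescaling on and off agree to round-off wherever both are finite.

A note on when underflow actually happens: per-pattern likelihoods of
data simulated from the model are bounded below by roughly `S^-N` (tips
are at most iid-uniform informative), so nucleotide models need
`N · log 4 > 745`, i.e. ≈ 540 taxa, before exact zeros can occur, whereas
codon models (`log 61 ≈ 4.1` per tip) underflow
catastrophically already at a few hundred taxa. The bundled `tall-tree`
demonstration fixture (512 taxa, unit branch lengths) therefore uses the
codon model.

**Variants.** `reference` is the plain numpy recursion. `batched` mirrors
the many-core organization of the computation: transposed transition
matrices are precomputed for all branches before the pre-order pass (an
option exists to transpose on the fly to bound memory), the pre-order
update runs as two sequenced stages (sibling matrix-vector stage, then the
transposed-matrix stage), the gradient accumulates state-specific
numerator/denominator entries serially across rate categories before a
parallelizable state reduction, and the state dimension may be zero-padded
to the next multiple of 16 (61 → 64). Padding adds exact zeros, so padded
and unpadded runs agree to round-off; the equivalence suite holds all
variants to 1e−12 of each other.

**Degenerate inputs.** `C = 1` and `N = 2` are supported. A pattern whose
mixture likelihood is exactly zero (impossible data) raises with the
pattern index rather than returning `−inf`; a zero gradient denominator
likewise raises — behavior chosen because silent zeros poison downstream
samplers.

## Oracles

Three independent validators, none sharing code with the gradient path:
per-branch matrix-derivative pruning (`O(N²)`), finite differences of the
log-likelihood (central, step 1e−6 by default; second-order one-sided at
the `b = 0` boundary, where a first-order stencil would not meet a 1e−5
comparison), and exhaustive enumeration over internal-node state
assignments (refused above 1e6 assignments). The randomized validation
grid spans `N ∈ {2,4,8,16}`, `S ∈ {4,61}`, `R ∈ {1,4}`,
`C ∈ {1,10,50}` with injected IUPAC/codon ambiguity and a zero-length
branch — sizes chosen so the full tripled comparison runs in well under a
minute while covering every shape regime the engine branches on.

## Synthetic data

The simulator realizes exactly the engine's model: per column a rate
category from `P(γ_r)`, a root state from `π`, then child states from the
rows of `P⁽ʳ⁾(b)` in pre-order. One seeded stream drives everything in a
documented order (all categories, all root states, then branch-by-branch
transitions), so outputs are byte-reproducible. Random trees come from
sequential random coalescence of lineages with i.i.d. branch lengths
(default exponential, mean 0.1 — a typical scale for within-species or
viral data). What the generator does *not* emulate: indels and alignment
error, selection heterogeneity along the sequence, non-stationary or
non-homogeneous processes, and sampling-time structure. Passing tests
therefore certify the arithmetic of likelihood and gradient under the
stated model, not robustness to model misspecification.

## Inference demos

The ML fitter runs L-BFGS-B in log-branch-length space with the analytic
gradient. The HMC sampler is deliberately minimal: log-space with the
Jacobian term, identity mass matrix, plain leapfrog, no adaptation;
exponential prior (mean 0.1) on each branch length. Defaults
(ε = 0.05, L = 10) give high acceptance on the small demo problems; they
are not tuned per dataset.

Recovery checks compare the two root-child branches through their **sum**:
with a reversible model and stationary root prior the likelihood depends
on root-adjacent branches only through their total (pulley principle), so
the individual lengths are not identifiable and no estimator can recover
them separately. All other branches are compared individually, within 10%
relative error or three standard errors (from the observed information, or
posterior SDs for the HMC check) — the allowance matters for very short
branches, where a handful of expected substitutions in the whole alignment
makes 10% relative precision information-theoretically unreachable.

## Known limitations

* Gradients are with respect to branch lengths only; chain-rule conversion
  to node-height or clock-rate parameterizations, and gradients for
  substitution-model parameters (κ, ω, frequencies, gamma shape), are the
  caller's concern / out of scope.
* One partition per run; multi-gene analyses are multiple runs.
* Pre-order partials are unscaled by design; an overflow there (never
  observed in the suites) raises rather than being renormalized.
* The batched variant is a faithful CPU analog of a many-core layout, not
  a GPU implementation; no device code is included.
* Topology search/proposals and full Bayesian workflows (clock models,
  coalescent priors) are out of scope.
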