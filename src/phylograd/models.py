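"""Substitution models.

Continuous-time Markov chain (CTMC) infinitesimal generators for nucleotide
(GTR and submodels), codon (kappa/omega), and Markov-modulated compositions;
discrete-gamma among-site rate heterogeneity; finite-time transition
probability matrices P(b) = exp(gamma * b * Q) and their branch-length
derivatives.

Generators are normalized (when requested) so that the expected number of
substitutions per unit time at stationarity is one, keeping branch lengths
in expected-substitution units.  Reversible generators expose a symmetric
eigendecomposition (via the pi^(1/2) similarity transform) that is computed
once and reused across all (rate category, branch length) pairs; general
generators fall back to scipy's scaling-and-squaring matrix exponential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from . import codes
from .exceptions import InvalidParameterError, NumericalError

NUCLEOTIDES = ("A", "C", "G", "T")

__all__ = [
    "GeneratorMatrix",
    "RateCategories",
    "TransitionMatrixSet",
    "gtr_generator",
    "jc69_generator",
    "hky_generator",
    "codon_generator",
    "markov_modulated_generator",
    "discrete_gamma",
    "transition_probabilities",
    "transition_derivative",
    "transpose_for_preorder",
    "pad_matrix_set",
    "stationary_distribution",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneratorMatrix:
    """S x S CTMC infinitesimal generator with its stationary distribution.

    Attributes
    ----------
    entries
        The generator Q; off-diagonals are instantaneous rates, rows sum
        to zero.
    stationary
        Stationary probability vector pi with pi @ Q = 0.
    reversible
        Whether detailed balance pi_s Q_st = pi_t Q_ts holds; enables the
        symmetric-eigendecomposition exponential path.
    code_tag
        Genetic-code identifier for codon models, else None.
    state_labels
        Human-readable state symbols (nucleotides, codons, ...), used by
        the simulator and encoders.
    """

    entries: np.ndarray
    stationary: np.ndarray
    reversible: bool = False
    code_tag: str | None = None
    state_labels: tuple[str, ...] | None = None
    _decomposition: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def size(self) -> int:
        return self.entries.shape[0]

    def validate(self, atol_rowsum: float = 1e-12, atol_stationary: float = 1e-10) -> None:
        Q, pi = self.entries, self.stationary
        S = self.size
        if Q.shape != (S, S) or pi.shape != (S,):
            raise InvalidParameterError("generator/stationary shape mismatch")
        off = Q[~np.eye(S, dtype=bool)]
        if np.any(off < -1e-14):
            raise InvalidParameterError("negative off-diagonal rate in generator")
        if np.max(np.abs(Q.sum(axis=1))) > atol_rowsum * max(1.0, np.abs(Q).max()):
            raise InvalidParameterError("generator rows do not sum to zero")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("stationary vector is not a probability vector")
        if np.max(np.abs(pi @ Q)) > atol_stationary * max(1.0, np.abs(Q).max()):
            raise InvalidParameterError("pi . Q != 0: stationary vector inconsistent")

    def mean_rate(self) -> float:
        """Expected substitutions per unit time at stationarity,
        -sum_s pi_s Q_ss."""
        return float(-np.dot(self.stationary, np.diag(self.entries)))

    def _symmetric_decomposition(self):
        """Eigendecomposition of D Q D^-1 (D = diag(sqrt(pi))), which is
        symmetric for reversible Q.  Cached; reused for every (rate, branch)."""
        if self._decomposition is None:
            d = np.sqrt(self.stationary)
            B = (d[:, None] * self.entries) / d[None, :]
            w, U = np.linalg.eigh(0.5 * (B + B.T))
            # P(t) = D^-1 U exp(w t) U' D
            self._decomposition = (w, U / d[:, None], U.T * d[None, :])
        return self._decomposition


@dataclass
class RateCategories:
    """Finite mixture of rate scalars approximating among-site rate variation."""

    rates: np.ndarray
    weights: np.ndarray

    @property
    def count(self) -> int:
        return len(self.rates)

    def validate(self) -> None:
        if self.count < 1:
            raise InvalidParameterError("need at least one rate category")
        if np.any(self.rates < 0):
            raise InvalidParameterError("negative rate scalar")
        if np.any(np.diff(self.rates) < 0):
            raise InvalidParameterError("rate scalars must be ascending")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("category weights must sum to 1")


def single_rate() -> RateCategories:
    """The degenerate one-category mixture (no rate heterogeneity)."""
    return RateCategories(rates=np.array([1.0]), weights=np.array([1.0]))


@dataclass
class TransitionMatrixSet:
    """Per-rate-category finite-time transition matrices for one branch.

    ``matrices`` has shape (R, pad, pad); rows/columns beyond ``state_count``
    are zero padding (an option of the batched engine; the reference engine
    never pads).
    """

    matrices: np.ndarray
    state_count: int
    transposed: bool = False

    @property
    def pad_width(self) -> int:
        return self.matrices.shape[-1]


# ---------------------------------------------------------------------------
# generator constructors
# ---------------------------------------------------------------------------


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary vector of a generator, via the null space of Q'."""
    S = Q.shape[0]
    # solve pi Q = 0, sum(pi) = 1 as a least-squares-free linear system
    A = np.vstack([Q.T, np.ones((1, S))])
    b = np.zeros(S + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _finalize(Q: np.ndarray, pi: np.ndarray, normalize: bool, **kw) -> GeneratorMatrix:
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    if normalize:
        mu = -np.dot(pi, np.diag(Q))
        if mu <= 0:
            raise InvalidParameterError("generator has zero mean rate; cannot normalize")
        Q = Q / mu
    return GeneratorMatrix(entries=Q, stationary=pi, **kw)


def gtr_generator(
    exchangeabilities, base_frequencies, normalize: bool = True
) -> GeneratorMatrix:
    """General time-reversible nucleotide generator.

    Parameters
    ----------
    exchangeabilities
        Six symmetric rates in the order (AC, AG, AT, CG, CT, GT).
    base_frequencies
        Stationary nucleotide frequencies (A, C, G, T), strictly positive.
    normalize
        Rescale to one expected substitution per unit time.
    """
    r = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_frequencies, dtype=float)
    if r.shape != (6,) or np.any(r < 0):
        raise InvalidParameterError("need 6 nonnegative exchangeabilities (AC,AG,AT,CG,CT,GT)")
    if not np.any(r > 0):
        raise InvalidParameterError("at least one exchangeability must be positive")
    if pi.shape != (4,) or np.any(pi <= 0):
        raise InvalidParameterError("need 4 strictly positive base frequencies")
    if abs(pi.sum() - 1.0) > 1e-8:
        raise InvalidParameterError("base frequencies must sum to 1")
    pi = pi / pi.sum()

    R = np.zeros((4, 4))
    R[0, 1], R[0, 2], R[0, 3] = r[0], r[1], r[2]
    R[1, 2], R[1, 3] = r[3], r[4]
    R[2, 3] = r[5]
    R = R + R.T
    Q = R * pi[None, :]
    return _finalize(
        Q, pi, normalize, reversible=True, state_labels=NUCLEOTIDES
    )


def jc69_generator() -> GeneratorMatrix:
    """Jukes-Cantor: equal exchangeabilities, equal frequencies, mean rate 1."""
    return gtr_generator(np.ones(6), np.full(4, 0.25))


def hky_generator(kappa: float, base_frequencies, normalize: bool = True) -> GeneratorMatrix:
    """HKY85: transitions (AG, CT) scaled by kappa relative to transversions."""
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    return gtr_generator([1.0, kappa, 1.0, 1.0, kappa, 1.0], base_frequencies, normalize)


def codon_generator(
    kappa: float,
    omega: float,
    codon_frequencies=None,
    genetic_code: str = "universal",
) -> GeneratorMatrix:
    """Codon substitution generator with transition:transversion ratio kappa
    and nonsynonymous:synonymous ratio omega (dN/dS).

    The rate from codon I to codon J is nonzero only when they differ at
    exactly one nucleotide position, and then equals

        pi_J * kappa^[transition] * omega^[nonsynonymous],

    with the target-codon-frequency multiplier pi_J.  Stop codons are
    excluded from the state space; the state count S is the number of sense
    codons under ``genetic_code`` (61 for the universal code, 60 for the
    vertebrate mitochondrial code).  The generator is reversible and always
    normalized to mean rate one.
    """
    if kappa <= 0:
        raise InvalidParameterError("kappa must be positive")
    if omega < 0:
        raise InvalidParameterError("omega must be nonnegative")
    senses = codes.sense_codons(genetic_code)
    aa = codes.genetic_code_table(genetic_code)
    S = len(senses)
    if codon_frequencies is None:
        pi = np.full(S, 1.0 / S)
    else:
        pi = np.asarray(codon_frequencies, dtype=float)
        if pi.shape != (S,):
            raise InvalidParameterError(
                f"codon frequency vector has length {pi.shape}, expected {S} "
                f"for genetic code {genetic_code!r}"
            )
        if np.any(pi <= 0):
            raise InvalidParameterError("codon frequencies must be strictly positive")
        pi = pi / pi.sum()

    Q = np.zeros((S, S))
    for i, ci in enumerate(senses):
        for j, cj in enumerate(senses):
            if i == j:
                continue
            pos = codes.single_nucleotide_difference(ci, cj)
            if pos is None:
                continue
            rate = pi[j]
            if codes.is_transition(ci[pos], cj[pos]):
                rate *= kappa
            if aa[ci] != aa[cj]:
                rate *= omega
            Q[i, j] = rate
    return _finalize(
        Q,
        pi,
        normalize=True,
        reversible=True,
        code_tag=genetic_code,
        state_labels=tuple(senses),
    )


def markov_modulated_generator(
    components: list[GeneratorMatrix],
    switching,
    normalize: bool = True,
) -> GeneratorMatrix:
    """Markov-modulated composition of K equally sized component CTMCs.

    The composite state is (component, character); within-component blocks
    are the component generators and between-component blocks are
    ``switching[a, b] * I``.  Two 61-state codon components give the
    122-state composition.  The composite is generally not reversible, so
    transition probabilities use the scaling-and-squaring path.
    """
    if len(components) < 2:
        raise InvalidParameterError("need at least two components")
    S0 = components[0].size
    if any(c.size != S0 for c in components):
        raise InvalidParameterError("component generators must have equal state counts")
    K = len(components)
    sw = np.asarray(switching, dtype=float)
    if sw.shape != (K, K) or np.any(sw[~np.eye(K, dtype=bool)] < 0):
        raise InvalidParameterError("switching table must be KxK with nonnegative off-diagonals")

    S = K * S0
    Q = np.zeros((S, S))
    for a in range(K):
        sl_a = slice(a * S0, (a + 1) * S0)
        Q[sl_a, sl_a] = components[a].entries
        for b in range(K):
            if a == b:
                continue
            Q[sl_a, b * S0 : (b + 1) * S0] = sw[a, b] * np.eye(S0)
    # diagonal is recomputed from the off-diagonal rows (component rates plus
    # switching mass) inside _finalize; normalization rescales Q uniformly so
    # the composite stationary distribution is computed first
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    pi = stationary_distribution(Q)
    labels = tuple(
        f"{lab}.{a}"
        for a, c in enumerate(components)
        for lab in (c.state_labels or [str(s) for s in range(S0)])
    )
    return _finalize(Q, pi, normalize, reversible=False, state_labels=labels)


# ---------------------------------------------------------------------------
# rate heterogeneity
# ---------------------------------------------------------------------------


def discrete_gamma(shape: float, category_count: int) -> RateCategories:
    """Equal-weight discrete-gamma rate categories.

    Each category rate is the mean of the gamma(shape, shape) distribution
    over the corresponding equal-probability quantile band (the category-mean
    discretization), then renormalized to mean exactly one.
    """
    if shape <= 0:
        raise InvalidParameterError("gamma shape must be positive")
    R = int(category_count)
    if R < 1:
        raise InvalidParameterError("need at least one category")
    if R == 1:
        return single_rate()
    cuts = _gamma_dist.ppf(np.arange(1, R) / R, a=shape, scale=1.0 / shape)
    # integral of x * pdf over a band equals the regularized incomplete
    # gamma with shape+1 evaluated at the band edges (unit-mean scaling)
    F1 = np.concatenate([[0.0], gammainc(shape + 1.0, shape * cuts), [1.0]])
    rates = R * np.diff(F1)
    rates = rates / np.mean(rates)
    return RateCategories(rates=rates, weights=np.full(R, 1.0 / R))


# ---------------------------------------------------------------------------
# transition matrices
# ---------------------------------------------------------------------------


def _expm_gbQ(Q: GeneratorMatrix, t: float) -> np.ndarray:
    """exp(t Q) for one effective time t = gamma * b."""
    if t == 0.0:
        return np.eye(Q.size)
    if Q.reversible:
        w, V, Vinv = Q._symmetric_decomposition()
        P = (V * np.exp(w * t)[None, :]) @ Vinv
    else:
        P = expm(t * Q.entries)
    return P


def transition_probabilities(
    Q: GeneratorMatrix, rates: RateCategories, branch_length: float
) -> TransitionMatrixSet:
    """P^(r)(b) = exp(gamma_r * b * Q) for every rate category r."""
    b = float(branch_length)
    if not np.isfinite(b) or b < 0:
        raise InvalidParameterError(f"branch length must be finite and >= 0, got {b}")
    mats = np.empty((rates.count, Q.size, Q.size))
    for r, g in enumerate(rates.rates):
        mats[r] = _expm_gbQ(Q, g * b)
    if not np.all(np.isfinite(mats)):
        raise NumericalError("non-finite transition probabilities after exponentiation")
    if mats.min() < -1e-10:
        raise NumericalError("significantly negative transition probability")
    np.clip(mats, 0.0, None, out=mats)  # round-off negatives from the eigen path
    return TransitionMatrixSet(matrices=mats, state_count=Q.size)


def transition_derivative(
    Q: GeneratorMatrix, rates: RateCategories, branch_length: float
) -> TransitionMatrixSet:
    """d/db P^(r)(b) = gamma_r * Q * exp(gamma_r * b * Q)."""
    b = float(branch_length)
    if not np.isfinite(b) or b < 0:
        raise InvalidParameterError(f"branch length must be finite and >= 0, got {b}")
    mats = np.empty((rates.count, Q.size, Q.size))
    for r, g in enumerate(rates.rates):
        mats[r] = g * (Q.entries @ _expm_gbQ(Q, g * b))
    if not np.all(np.isfinite(mats)):
        raise NumericalError("non-finite transition derivative")
    return TransitionMatrixSet(matrices=mats, state_count=Q.size)


def transpose_for_preorder(matrices: TransitionMatrixSet) -> TransitionMatrixSet:
    """Swap the state axes of every (branch, rate) matrix; padding is
    preserved (zero rows become zero columns)."""
    return TransitionMatrixSet(
        matrices=np.ascontiguousarray(matrices.matrices.swapaxes(-1, -2)),
        state_count=matrices.state_count,
        transposed=not matrices.transposed,
    )


def pad_matrix_set(matrices: TransitionMatrixSet, pad_width: int | None = None) -> TransitionMatrixSet:
    """Embed matrices into a zero-padded state dimension.

    Default pad width is the next multiple of 16 at or above S (61 -> 64),
    mirroring aligned-memory batching; entries beyond S are exactly zero.
    """
    S = matrices.state_count
    if pad_width is None:
        pad_width = -(-S // 16) * 16
    if pad_width < matrices.pad_width:
        raise InvalidParameterError("pad_width smaller than current matrix dimension")
    if pad_width == matrices.pad_width:
        return matrices
    shape = matrices.matrices.shape[:-2] + (pad_width, pad_width)
    out = np.zeros(shape)
    out[..., : matrices.pad_width, : matrices.pad_width] = matrices.matrices
    return TransitionMatrixSet(matrices=out, state_count=S, transposed=matrices.transposed)
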