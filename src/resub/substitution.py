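"""Continuous-time Markov substitution models over finite alphabets.

A substitution process is parameterised by a symmetric exchangeability
matrix ``r`` and an equilibrium frequency vector ``pi`` (a general
time-reversible, or GTR-style, parameterisation).  The instantaneous rate
matrix is ``Q[i,j] = r[i,j] * pi[j]`` for ``i != j`` with diagonal entries
chosen so rows sum to zero, and is normalised so that the expected number
of substitutions per site per unit time at equilibrium is one.  Transition
probabilities over a genetic distance ``tau`` are the matrix exponential
``P(tau) = expm(q(Q) * tau)``.

Site-to-site rate variation uses the standard discrete-gamma construction:
``k`` equal-probability categories whose rates are the means of the gamma
density over the category quantile intervals, rescaled to average one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm
from scipy.special import gammainc, gammaincinv

__all__ = [
    "PROTEIN_STATES",
    "Alphabet",
    "SubstitutionBasis",
    "RateMatrix",
    "TransitionMatrix",
    "SiteRateModel",
    "build_rate_matrix",
    "normalize_rate_matrix",
    "transition_matrix",
    "discrete_gamma_rates",
    "read_paml_matrix",
    "protein_alphabet",
]

#: The 20 standard amino acids in one-letter alphabetical order.  All
#: protein matrices in this package are indexed in this order.
PROTEIN_STATES = tuple("ACDEFGHIKLMNPQRSTVWY")

# Ambiguity codes mapped to the sets of states they may represent.  Fully
# ambiguous codes ('-', 'X', '?') map to the whole alphabet and are handled
# separately by callers.
AMBIGUITY_SETS = {
    "B": ("D", "N"),
    "Z": ("E", "Q"),
    "J": ("I", "L"),
}


class ValidationError(ValueError):
    """Raised when a model component violates its structural invariants."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered finite state space of single-character labels."""

    states: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise ValidationError("alphabet needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"duplicate state labels in {self.states}")

    @property
    def size(self) -> int:
        return len(self.states)

    def index(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise ValidationError(
                f"state {label!r} not in alphabet {''.join(self.states)}"
            ) from None

    def __len__(self) -> int:
        return self.size

    def __iter__(self):
        return iter(self.states)


def protein_alphabet() -> Alphabet:
    """The canonical 20-state amino acid alphabet."""
    return Alphabet(PROTEIN_STATES)


@dataclass(frozen=True)
class SubstitutionBasis:
    """Exchangeabilities and equilibrium frequencies over an alphabet.

    Parameters
    ----------
    alphabet
        The state space.
    exchangeabilities
        Symmetric ``m x m`` array of non-negative reals; the diagonal is
        ignored.
    frequencies
        Length-``m`` probability simplex with strictly positive entries.
    """

    alphabet: Alphabet
    exchangeabilities: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self) -> None:
        m = self.alphabet.size
        r = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.frequencies, dtype=float)
        if r.shape != (m, m):
            raise ValidationError(f"exchangeability matrix must be {m}x{m}, got {r.shape}")
        if pi.shape != (m,):
            raise ValidationError(f"frequency vector must have length {m}, got {pi.shape}")
        asym = np.argwhere(~np.isclose(r, r.T, rtol=0, atol=1e-12))
        if asym.size:
            i, j = asym[0]
            raise ValidationError(
                f"exchangeabilities must be symmetric; r[{i},{j}]={r[i, j]} != r[{j},{i}]={r[j, i]}"
            )
        off = r[~np.eye(m, dtype=bool)]
        if np.any(off < 0):
            raise ValidationError("exchangeabilities must be non-negative")
        if np.any(pi <= 0):
            k = int(np.argmin(pi))
            raise ValidationError(f"frequency pi[{k}]={pi[k]} must be positive")
        if abs(pi.sum() - 1.0) > 1e-12:
            raise ValidationError(f"frequencies sum to {pi.sum()!r}, expected 1 within 1e-12")
        object.__setattr__(self, "exchangeabilities", r)
        object.__setattr__(self, "frequencies", pi)

    @property
    def size(self) -> int:
        return self.alphabet.size


@dataclass(frozen=True)
class RateMatrix:
    """An instantaneous rate matrix (rows sum to zero).

    ``normalized`` records whether the mean outgoing rate at equilibrium,
    ``-sum_i pi[i] Q[i,i]``, equals one substitution per unit time.
    """

    entries: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        Q = np.asarray(self.entries, dtype=float)
        m = Q.shape[0]
        if Q.shape != (m, m):
            raise ValidationError("rate matrix must be square")
        off = Q[~np.eye(m, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValidationError("off-diagonal rates must be non-negative")
        rows = Q.sum(axis=1)
        if np.any(np.abs(rows) > 1e-10):
            raise ValidationError(f"rate matrix rows must sum to 0; worst residual {np.abs(rows).max()}")
        object.__setattr__(self, "entries", Q)

    @property
    def size(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class TransitionMatrix:
    """A row-stochastic matrix of state transition probabilities.

    Rows and columns may be indexed by different alphabets: transition
    matrices that span a coding-alphabet change are rectangular, with rows
    on the older (reduced) alphabet and columns on the younger (full) one.
    """

    entries: np.ndarray
    row_states: Alphabet
    col_states: Alphabet

    def __post_init__(self) -> None:
        P = np.asarray(self.entries, dtype=float)
        if P.shape != (self.row_states.size, self.col_states.size):
            raise ValidationError(
                f"transition matrix shape {P.shape} does not match state spaces "
                f"({self.row_states.size}, {self.col_states.size})"
            )
        if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        rows = P.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-9):
            raise ValidationError(f"transition matrix rows must sum to 1; worst row sum {rows[np.argmax(np.abs(rows-1))]}")
        object.__setattr__(self, "entries", P)


@dataclass(frozen=True)
class SiteRateModel:
    """Discrete-gamma site-rate heterogeneity.

    ``rates`` are the per-category rate multipliers (non-decreasing, mean
    one); categories carry equal weight.
    """

    shape: float
    n_categories: int = 4
    rates: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValidationError("gamma shape must be positive")
        if self.n_categories < 1:
            raise ValidationError("need at least one rate category")
        rates = np.asarray(self.rates, dtype=float)
        if abs(rates.mean() - 1.0) > 1e-9:
            raise ValidationError("category rates must average 1")
        if np.any(np.diff(rates) < -1e-12):
            raise ValidationError("category rates must be non-decreasing")
        object.__setattr__(self, "rates", rates)


# ---------------------------------------------------------------------------
# operations


def build_rate_matrix(basis: SubstitutionBasis) -> RateMatrix:
    """Assemble the (unnormalised) rate matrix ``Q = r * diag(pi)``.

    Off-diagonals are ``r[i,j] * pi[j]``; each diagonal is the negated sum
    of its off-diagonal row, so rows sum to zero.
    """
    r = basis.exchangeabilities
    pi = basis.frequencies
    Q = r * pi[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(Q, normalized=False)


def normalize_rate_matrix(Q: RateMatrix, pi: np.ndarray) -> RateMatrix:
    """Rescale ``Q`` so the mean outgoing rate at equilibrium is 1.

    The normaliser is ``-sum_i pi[i] Q[i,i]``, the expected number of
    substitutions per site per unit time under frequencies ``pi``.
    """
    pi = np.asarray(pi, dtype=float)
    mu = -float(pi @ np.diag(Q.entries))
    if mu <= 0:
        raise ValidationError(f"degenerate model: mean substitution rate {mu} is not positive")
    return RateMatrix(Q.entries / mu, normalized=True)


def normalized_rate_matrix(basis: SubstitutionBasis) -> RateMatrix:
    """Convenience: build and normalise in one step."""
    return normalize_rate_matrix(build_rate_matrix(basis), basis.frequencies)


def transition_matrix(Qn: RateMatrix, tau: float, alphabet: Alphabet | None = None) -> TransitionMatrix:
    """Transition probabilities ``P(tau) = expm(Q * tau)``.

    ``tau`` is a genetic distance in expected substitutions per site.
    Uses the dense Pade-approximant matrix exponential; the per-process
    likelihood engine uses a cached spectral decomposition instead (the two
    agree to well below the tolerances asserted anywhere in this package).
    """
    if tau < 0:
        raise ValueError(f"genetic distance must be non-negative, got {tau}")
    P = expm(Qn.entries * tau)
    if not np.all(np.isfinite(P)):
        cond = np.linalg.cond(Qn.entries)
        raise FloatingPointError(
            f"matrix exponential produced non-finite entries (tau={tau}, cond(Q)={cond:g})"
        )
    # clip exponential round-off; deviations are ~1e-16
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    m = P.shape[0]
    ab = alphabet if alphabet is not None else Alphabet(tuple(chr(65 + i) for i in range(m)))
    return TransitionMatrix(P, ab, ab)


def discrete_gamma_rates(shape: float, k: int = 4) -> SiteRateModel:
    """Discrete-gamma rate categories (mean-of-interval discretisation).

    The gamma density with mean 1 (shape ``a``, rate ``a``) is split into
    ``k`` equal-probability intervals; each category rate is the mean of
    the density over its interval, so the rates average exactly 1.
    """
    if shape <= 0:
        raise ValidationError("gamma shape must be positive")
    if k < 1:
        raise ValidationError("need at least one category")
    if k == 1:
        return SiteRateModel(shape, 1, np.array([1.0]))
    a = float(shape)
    # quantile boundaries of Gamma(a, rate=a)
    probs = np.arange(1, k) / k
    cut = gammaincinv(a, probs) / a
    # E[X; X in (lo, hi)] for Gamma(a, rate=a) equals P(a+1, a*hi) - P(a+1, a*lo)
    upper = np.concatenate([gammainc(a + 1, a * cut), [1.0]])
    lower = np.concatenate([[0.0], gammainc(a + 1, a * cut)])
    rates = (upper - lower) * k
    rates = rates / rates.mean()
    return SiteRateModel(shape, k, rates)


# ---------------------------------------------------------------------------
# spectral machinery shared by the likelihood engine and simulator


class EigenSystem:
    """Spectral decomposition of a reversible normalised rate matrix.

    For a reversible process, ``diag(sqrt(pi)) Q diag(1/sqrt(pi))`` is
    symmetric, so ``Q = A diag(w) Ainv`` with real eigenvalues ``w`` and
    well-conditioned eigenvectors.  ``P(tau) = A diag(exp(w tau)) Ainv``
    can then be evaluated for whole arrays of distances at once.
    """

    def __init__(self, Qn: RateMatrix, pi: np.ndarray):
        pi = np.asarray(pi, dtype=float)
        s = np.sqrt(pi)
        B = (Qn.entries * s[:, None]) / s[None, :]
        B = 0.5 * (B + B.T)  # symmetrise round-off
        w, U = np.linalg.eigh(B)
        self.w = w
        self.A = U / s[:, None]
        self.Ainv = U.T * s[None, :]
        self.pi = pi

    def probabilities(self, tau) -> np.ndarray:
        """P(tau) for scalar or array ``tau``; result shape ``tau.shape + (m, m)``."""
        tau = np.asarray(tau, dtype=float)
        ew = np.exp(np.multiply.outer(tau, self.w))
        P = (self.A * ew[..., None, :]) @ self.Ainv
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=-1, keepdims=True)
        return P


# ---------------------------------------------------------------------------
# empirical matrix input


def read_paml_matrix(path) -> SubstitutionBasis:
    """Read a PAML-style amino acid rate file (lower triangle + frequencies).

    The format is 19 rows of lower-triangular exchangeabilities followed by
    a row (or rows) of 20 equilibrium frequencies, with blank lines and
    trailing comments permitted — the layout used by LG, WAG and friends.
    """
    with open(path) as fh:
        tokens: list[float] = []
        for line in fh:
            for tok in line.split():
                try:
                    tokens.append(float(tok))
                except ValueError:
                    break  # trailing comment: ignore rest of line
            if len(tokens) >= 190 + 20:
                break
    if len(tokens) < 190 + 20:
        raise ValidationError(
            f"expected 190 exchangeabilities + 20 frequencies, found {len(tokens)} numbers"
        )
    tri = tokens[:190]
    freqs = np.array(tokens[190:210])
    m = 20
    r = np.zeros((m, m))
    k = 0
    for i in range(1, m):
        for j in range(i):
            r[i, j] = r[j, i] = tri[k]
            k += 1
    freqs = freqs / freqs.sum()
    return SubstitutionBasis(protein_alphabet(), r, freqs)
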