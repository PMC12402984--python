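"""The two-epoch reduced-alphabet ("resub") substitution model.

Time runs backwards from the present.  The young epoch E1 = [0, te]
carries the full m-state alphabet with exchangeabilities r and
frequencies pi.  The old epoch E2 = (te, root] carries a reduced
(m-1)-state alphabet whose composition depends on the model indicator
``Is`` applied to a designated *cherry* of states (alpha, beta):

* Is = 0 — null: both epochs share the full alphabet.
* Is = 1 — refinement: alpha and beta were one merged low-specificity
  state in E2 (subfunctionalisation); the merged state sits in alpha's
  slot with frequency ``pi[alpha] + pi[beta]`` and frequency-weighted
  exchangeabilities.
* Is = 2 — expansion: beta is absent from E2 (neofunctionalisation);
  the remaining frequencies renormalise to sum to one.
* Is = 3 — expansion with the roles of alpha and beta swapped.

At the epoch boundary a row-stochastic (m-1) x m saltation matrix Xi
instantaneously transfers probability into the newly coded state: the
retained cherry state jumps to the new state with probability ``nu``,
and every other state leaks into the new state(s) in proportion to their
modern equilibrium frequencies.  A lineage spanning both epochs with
distance tau2 in E2 and tau1 in E1 has transition probabilities

    P(tau2, tau1) = expm(q(Q') tau2) @ Xi @ expm(q(Q) tau1),

a rectangular matrix with rows on the reduced (parent-side) alphabet and
columns on the full (child-side) alphabet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .substitution import (
    Alphabet,
    SubstitutionBasis,
    TransitionMatrix,
    ValidationError,
    normalized_rate_matrix,
    transition_matrix,
)

__all__ = [
    "ResubConfiguration",
    "ReducedBasis",
    "SaltationMatrix",
    "reduce_alphabet",
    "saltation_matrix",
    "epoch_transition_matrix",
    "root_frequencies",
]

REFINEMENT = 1
EXPANSION_DISCARD_BETA = 2
EXPANSION_DISCARD_ALPHA = 3


@dataclass(frozen=True)
class ResubConfiguration:
    """A cherry, a hypothesis indicator, and the boundary parameters.

    Parameters
    ----------
    alpha, beta
        Indices of the cherry states in the full alphabet.
    indicator
        Model case in {0, 1, 2, 3} (see module docstring).
    boundary_age
        Age ``te`` of the epoch boundary, in the tree's time units.
    saltation_fraction
        ``nu``, the proportion of retained-cherry-state characters that
        jump into the newly coded state at the boundary.
    """

    alpha: int
    beta: int
    indicator: int = 0
    boundary_age: float = 0.0
    saltation_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha == self.beta:
            raise ValidationError("cherry states alpha and beta must differ")
        if self.indicator not in (0, 1, 2, 3):
            raise ValidationError(f"model indicator must be in {{0,1,2,3}}, got {self.indicator}")
        if self.boundary_age < 0:
            raise ValidationError("boundary age te must be non-negative")
        if not 0.0 <= self.saltation_fraction <= 1.0:
            raise ValidationError("saltation fraction nu must lie in [0, 1]")

    @property
    def retained(self) -> int:
        """gamma1: the cherry index present in the old alphabet."""
        if self.indicator == 0:
            raise ValidationError("retained/discarded indices are undefined under the null case")
        return self.beta if self.indicator == EXPANSION_DISCARD_ALPHA else self.alpha

    @property
    def discarded(self) -> int:
        """gamma0: the cherry index absent from (or merged away in) the old alphabet."""
        if self.indicator == 0:
            raise ValidationError("retained/discarded indices are undefined under the null case")
        return self.alpha if self.indicator == EXPANSION_DISCARD_ALPHA else self.beta

    def replace(self, **kw) -> "ResubConfiguration":
        from dataclasses import replace

        return replace(self, **kw)


@dataclass(frozen=True)
class ReducedBasis:
    """The old-epoch substitution basis plus its mapping to the full alphabet.

    ``index_map[i]`` is the full-alphabet index that reduced index ``i``
    descends from (for the merged state under refinement, the slot of the
    retained index).  Under the null case the basis is the input itself
    and the map is the identity.
    """

    basis: SubstitutionBasis
    index_map: np.ndarray
    merged_label: str | None = None


def reduce_alphabet(basis: SubstitutionBasis, config: ResubConfiguration) -> ReducedBasis:
    """Build the reduced old-epoch basis for the configured hypothesis."""
    m = basis.size
    if not (0 <= config.alpha < m and 0 <= config.beta < m):
        raise ValidationError("cherry indices outside the alphabet")
    if config.indicator == 0:
        return ReducedBasis(basis, np.arange(m), None)

    g1, g0 = config.retained, config.discarded
    keep = [i for i in range(m) if i != g0]
    pi = basis.frequencies
    r = basis.exchangeabilities
    labels = list(basis.alphabet.states)

    if config.indicator == REFINEMENT:
        # merge g0 into g1, assumed at equilibrium between its sub-states
        pi_merged = pi[g1] + pi[g0]
        r_new = r.copy()
        for i in range(m):
            if i in (g0, g1):
                continue
            r_new[g1, i] = r_new[i, g1] = (r[g1, i] * pi[g1] + r[g0, i] * pi[g0]) / pi_merged
        pi_new = pi.copy()
        pi_new[g1] = pi_merged
        r_red = r_new[np.ix_(keep, keep)]
        pi_red = pi_new[keep]
        a, b = labels[config.alpha], labels[config.beta]
        merged = f"{a}/{b}"
        labels_red = [merged if i == g1 else labels[i] for i in keep]
    else:
        # expansion: drop g0 and renormalise frequencies
        r_red = r[np.ix_(keep, keep)]
        pi_red = pi[keep] / (1.0 - pi[g0])
        merged = None
        labels_red = [labels[i] for i in keep]

    pi_red = pi_red / pi_red.sum()  # guard 1e-16 drift against the simplex invariant
    reduced = SubstitutionBasis(Alphabet(tuple(labels_red)), r_red, pi_red)
    return ReducedBasis(reduced, np.array(keep), merged)


@dataclass(frozen=True)
class SaltationMatrix:
    """Row-stochastic (m-1) x m boundary jump probabilities.

    Rows are indexed by the reduced (old, parent-side) alphabet and
    columns by the full (young, child-side) alphabet.
    """

    entries: np.ndarray
    row_states: Alphabet
    col_states: Alphabet

    def __post_init__(self) -> None:
        X = np.asarray(self.entries, dtype=float)
        rows = X.sum(axis=1)
        if np.any(np.abs(rows - 1) > 1e-12):
            raise ValidationError("saltation matrix rows must sum to 1")
        if np.any(X < 0) or np.any(X > 1):
            raise ValidationError("saltation entries must lie in [0, 1]")
        object.__setattr__(self, "entries", X)


def saltation_matrix(basis: SubstitutionBasis, config: ResubConfiguration) -> SaltationMatrix:
    """The tree-wide instantaneous jump matrix Xi at the epoch boundary.

    Under refinement every non-cherry row leaks ``pi[g0]`` into the new
    state and ``pi[g1]`` into the retained one; under expansion only the
    ``pi[g0]`` leak applies.  The retained-state row places ``nu`` on the
    new state and ``1 - nu`` on itself.
    """
    if config.indicator == 0:
        raise ValidationError("saltation is undefined under the null case (Is=0)")
    m = basis.size
    g1, g0 = config.retained, config.discarded
    nu = config.saltation_fraction
    pi = basis.frequencies
    red = reduce_alphabet(basis, config)
    keep = red.index_map
    X = np.zeros((m - 1, m))
    for row, full_i in enumerate(keep):
        if full_i == g1:
            X[row, g0] = nu
            X[row, g1] = 1.0 - nu
        elif config.indicator == REFINEMENT:
            X[row, g0] = pi[g0]
            X[row, g1] = pi[g1]
            X[row, full_i] = 1.0 - pi[g0] - pi[g1]
        else:
            X[row, g0] = pi[g0]
            X[row, full_i] = 1.0 - pi[g0]
    return SaltationMatrix(X, red.basis.alphabet, basis.alphabet)


def epoch_transition_matrix(
    basis: SubstitutionBasis,
    config: ResubConfiguration,
    tau2: float,
    tau1: float,
) -> TransitionMatrix:
    """Transition probabilities for a lineage spanning the epoch boundary.

    ``tau2`` is the genetic distance accumulated in the old epoch E2 and
    ``tau1`` the distance in the young epoch E1.  Each epoch's factor is
    normalised with its own equilibrium frequencies.  Under the null case
    the boundary is inert and this collapses to a single-epoch matrix over
    ``tau1 + tau2``.
    """
    if tau1 < 0 or tau2 < 0:
        raise ValueError("genetic distances must be non-negative")
    if config.indicator == 0:
        return transition_matrix(normalized_rate_matrix(basis), tau1 + tau2, basis.alphabet)
    red = reduce_alphabet(basis, config)
    P_old = transition_matrix(normalized_rate_matrix(red.basis), tau2, red.basis.alphabet)
    Xi = saltation_matrix(basis, config)
    P_young = transition_matrix(normalized_rate_matrix(basis), tau1, basis.alphabet)
    P = P_old.entries @ Xi.entries @ P_young.entries
    return TransitionMatrix(P, red.basis.alphabet, basis.alphabet)


def root_frequencies(
    basis: SubstitutionBasis, config: ResubConfiguration, root_age: float
) -> np.ndarray:
    """Stationary frequencies applied at the top of the tree.

    When the two-epoch model is active and the root (or origin) predates
    the boundary, the reduced-alphabet frequencies apply; otherwise the
    full-alphabet frequencies do.
    """
    if config.indicator > 0 and root_age > config.boundary_age:
        return reduce_alphabet(basis, config).basis.frequencies
    return basis.frequencies
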