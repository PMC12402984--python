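import numpy as np
import pytest

from resub import (
    Alphabet,
    ResubConfiguration,
    SubstitutionBasis,
    TimeTree,
)


@pytest.fixture
def toy_alphabet() -> Alphabet:
    """Three-state toy alphabet (x, W, Y) with W/Y the candidate cherry."""
    return Alphabet(("x", "W", "Y"))


@pytest.fixture
def toy_basis(toy_alphabet) -> SubstitutionBasis:
    """The worked-example basis: r(x,W)=1, r(x,Y)=2, r(W,Y)=3; pi=(0.6,0.1,0.3)."""
    r = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    pi = np.array([0.6, 0.1, 0.3])
    return SubstitutionBasis(toy_alphabet, r, pi)


@pytest.fixture
def toy_config() -> ResubConfiguration:
    """Expansion case of the worked example: discard W, retain Y."""
    return ResubConfiguration(
        alpha=1, beta=2, indicator=3, boundary_age=0.5, saltation_fraction=0.25
    )


@pytest.fixture
def one_taxon_tree() -> TimeTree:
    """Single leaf at the present with an origin (stem) at height 1."""
    return TimeTree(parent=[-1], heights=[0.0], labels=["A"], origin_height=1.0)


@pytest.fixture
def two_taxon_tree() -> TimeTree:
    """Two leaves, root at 0.5, origin at 1 (the toy site-pattern tree)."""
    return TimeTree(
        parent=[2, 2, -1], heights=[0.0, 0.0, 0.5], labels=["A", "B", None],
        origin_height=1.0,
    )


def random_basis(rng: np.random.Generator, m: int) -> SubstitutionBasis:
    """A random reversible basis on m states (positive frequencies)."""
    labels = tuple(chr(97 + i) for i in range(m))
    pi = rng.dirichlet(np.ones(m))
    pi = np.clip(pi, 1e-3, None)
    pi = pi / pi.sum()
    r = np.zeros((m, m))
    iu = np.triu_indices(m, 1)
    r[iu] = rng.exponential(1.0, len(iu[0])) + 0.05
    r = r + r.T
    return SubstitutionBasis(Alphabet(labels), r, pi)
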