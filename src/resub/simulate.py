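"""Birth-death tree simulation and forward sequence simulation.

Trees are drawn from a birth-death(-sampling) process conditioned on the
number of sampled extant taxa.  The default sampler uses the
point-process construction for the reconstructed process: with a uniform
prior on the time of origin, the origin age has closed-form CDF
``eta(t)^n`` and, given the origin, the n-1 speciation ages are i.i.d.
with CDF ``eta(s)/eta(t_or)``, where

    eta(t) = lam*rho*(1 - exp(-r t)) / (lam*rho + (lam*(1-rho) - mu) exp(-r t)),

r = lam - mu.  Ranked topologies are uniform and independent of the ages.
The same ``eta`` yields the tree prior density used by the MCMC sampler,
so prior-simulated trees and posterior tree samples are mutually
consistent by construction.  An alternative forward-time mode (via
dendropy) retains dated extinct tips for serially sampled analyses.

Sequences evolve forward in time down the tree under the two-epoch
substitution process: old-epoch segments use the reduced-alphabet
transition matrices, the boundary crossing applies one categorical draw
from the saltation matrix, and young segments use the full-alphabet
matrices.  Leaves always emit full-alphabet characters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import ResubConfiguration, reduce_alphabet, root_frequencies, saltation_matrix
from .likelihood import Alignment, ClockModel, TimeTree, split_branch_at_boundary
from .substitution import (
    EigenSystem,
    SiteRateModel,
    SubstitutionBasis,
    ValidationError,
    normalized_rate_matrix,
)

__all__ = [
    "BirthDeathParams",
    "SimulationRecipe",
    "SimulationError",
    "simulate_bd_tree",
    "simulate_alignment",
    "sample_from_prior",
    "log_bd_tree_prior",
    "expected_root_height",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BirthDeathParams:
    """Birth-death-sampling parameters.

    ``reproduction_number`` is the per-lineage reproduction number
    R0 = birth rate / death rate; ``sampling_fraction`` is the
    probability rho that an extant lineage is sampled.  The conditioned
    reconstructed-process sampler requires a supercritical process
    (R0 > 1).
    """

    birth_rate: float
    reproduction_number: float
    sampling_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0:
            raise ValidationError("birth rate must be positive")
        if self.reproduction_number <= 0:
            raise ValidationError("reproduction number must be positive")
        if not 0 < self.sampling_fraction <= 1:
            raise ValidationError("sampling fraction must lie in (0, 1]")

    @property
    def death_rate(self) -> float:
        return self.birth_rate / self.reproduction_number

    @property
    def net_rate(self) -> float:
        return self.birth_rate - self.death_rate


def _eta_terms(params: BirthDeathParams):
    lam, mu, rho = params.birth_rate, params.death_rate, params.sampling_fraction
    r = lam - mu
    if r <= 0:
        raise ValidationError(
            "conditioned birth-death sampling requires a supercritical process (R0 > 1)"
        )
    A = rho * lam
    B = lam * (1 - rho) - mu
    return lam, mu, rho, r, A, B


def _eta(t, params: BirthDeathParams):
    lam, mu, rho, r, A, B = _eta_terms(params)
    z = np.exp(-r * np.asarray(t, dtype=float))
    return lam * rho * (1 - z) / (A + B * z)


def _eta_inv(u, params: BirthDeathParams):
    lam, mu, rho, r, A, B = _eta_terms(params)
    u = np.asarray(u, dtype=float)
    z = (lam * rho - u * A) / (u * B + lam * rho)
    return -np.log(z) / r


def _log_p1(t, params: BirthDeathParams):
    """log p1(t): probability one lineage leaves exactly one sampled descendant."""
    lam, mu, rho, r, A, B = _eta_terms(params)
    t = np.asarray(t, dtype=float)
    return np.log(rho) + 2 * np.log(r) - r * t - 2 * np.log(A + B * np.exp(-r * t))


def log_bd_tree_prior(tree: TimeTree, params: BirthDeathParams) -> float:
    """Log density of internal node ages on a fixed labelled topology.

    Conditioned on the number of sampled extant tips with a uniform prior
    on the origin time (origin marginalised out), the density is
    proportional to ``prod_i lam * p1(h_i) * (1 - eta(h_root))`` over the
    internal node ages, subject to parent-above-child constraints.
    """
    lam = params.birth_rate
    h = tree.heights[tree.internal_nodes()]
    root_h = tree.heights[tree.root]
    eta_root = float(_eta(root_h, params))
    if eta_root >= 1.0:
        return -np.inf
    return float(np.sum(np.log(lam) + _log_p1(h, params)) + np.log1p(-eta_root))


def expected_root_height(params: BirthDeathParams, n: int) -> float:
    """Mean root age of the conditioned reconstructed process (oracle-free).

    The marginal root-age CDF is ``G(s) = n eta^{n-1} - (n-1) eta^n``;
    the mean is the integral of ``1 - G`` computed by quadrature.
    """
    from scipy.integrate import quad

    def surv(s):
        e = _eta(s, params)
        return 1.0 - (n * e ** (n - 1) - (n - 1) * e**n)

    val, _ = quad(surv, 0, np.inf, limit=200)
    return float(val)


def _point_process_tree(ages: np.ndarray, labels: list[str], rng: np.random.Generator) -> TimeTree:
    """Assemble a ranked tree from n-1 speciation ages (point process)."""
    n = len(ages) + 1
    order = rng.permutation(n)
    tip_labels = [labels[i] for i in order]
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=int)
    heights = np.zeros(n_nodes)
    node_labels: list[str | None] = [None] * n_nodes
    for i in range(n):
        node_labels[i] = tip_labels[i]
    # clusters[i] is the current subtree root between gap i and i+1
    clusters = list(range(n))
    gap_ages = list(ages)
    next_node = n
    while len(clusters) > 1:
        k = int(np.argmin(gap_ages))
        a, b = clusters[k], clusters[k + 1]
        parent[a] = parent[b] = next_node
        heights[next_node] = gap_ages[k]
        clusters[k : k + 2] = [next_node]
        gap_ages.pop(k)
        next_node += 1
    return TimeTree(parent, heights, node_labels)


def simulate_bd_tree(
    params: BirthDeathParams,
    n_taxa: int,
    seed: int | np.random.Generator,
    retain_extinct: bool = False,
    max_tries: int = 1000,
) -> TimeTree:
    """Simulate a rooted time-tree with ``n_taxa`` sampled extant leaves.

    By default uses the exact point-process sampler for the reconstructed
    (extant-only) process.  With ``retain_extinct=True`` the tree is
    grown forward in time instead (via dendropy) and dated non-extant
    tips are kept, for serially sampled analyses.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_taxa < 2:
        raise ValidationError("need at least two taxa")
    if not retain_extinct:
        origin = float(_eta_inv(rng.random() ** (1.0 / n_taxa), params))
        ages = np.sort(_eta_inv(rng.random(n_taxa - 1) * _eta(origin, params), params))
        labels = [f"t{i + 1}" for i in range(n_taxa)]
        tree = _point_process_tree(ages, labels, rng)
        return tree
    return _forward_bd_tree(params, n_taxa, rng, max_tries)


def _forward_bd_tree(
    params: BirthDeathParams, n_taxa: int, rng: np.random.Generator, max_tries: int
) -> TimeTree:
    import random as _random

    from dendropy.model import birthdeath

    pyrng = _random.Random(int(rng.integers(2**31)))
    attempts = 0
    while attempts < max_tries:
        attempts += 1
        try:
            # GSA conditioning: grow past n_taxa and sample a time at which
            # exactly n_taxa lineages are extant (avoids the zero-length
            # terminal cherry of stop-at-the-Nth-birth simulation)
            dtree = birthdeath.birth_death_tree(
                birth_rate=params.birth_rate,
                death_rate=params.death_rate,
                num_extant_tips=n_taxa,
                gsa_ntax=n_taxa + 10,
                is_retain_extinct_tips=True,
                rng=pyrng,
            )
        except Exception:
            continue
        tree = _from_dendropy(dtree)
        if tree is not None:
            return tree
    raise SimulationError(
        f"birth-death conditioning on {n_taxa} extant taxa failed after {attempts} attempts"
    )


def _from_dendropy(dtree) -> TimeTree | None:
    nodes = list(dtree.preorder_node_iter())
    # reject unifurcations (e.g. a stem the simulator left at the root)
    for nd in nodes:
        if len(nd.child_nodes()) == 1:
            return None
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.array(
        [index[id(nd.parent_node)] if nd.parent_node else -1 for nd in nodes], dtype=int
    )
    depth = np.zeros(len(nodes))
    for nd in nodes:
        if nd.parent_node is not None:
            depth[index[id(nd)]] = depth[index[id(nd.parent_node)]] + (nd.edge.length or 0.0)
    heights = depth.max() - depth
    heights[np.abs(heights) < 1e-9] = 0.0
    labels: list[str | None] = []
    extant_i = extinct_i = 0
    for nd in nodes:
        if nd.is_leaf():
            if heights[index[id(nd)]] <= 1e-9:
                extant_i += 1
                labels.append(f"t{extant_i}")
            else:
                extinct_i += 1
                labels.append(f"f{extinct_i}")
        else:
            labels.append(None)
    try:
        return TimeTree(parent, heights, labels)
    except ValidationError:
        return None


# ---------------------------------------------------------------------------
# sequence simulation


@dataclass(frozen=True)
class SimulationRecipe:
    """All ingredients needed to simulate one alignment."""

    basis: SubstitutionBasis
    config: ResubConfiguration
    site_model: SiteRateModel
    clock: ClockModel
    n_sites: int
    seed: int
    bd: BirthDeathParams | None = None

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValidationError("need at least one site")


def _draw_states(P: np.ndarray, current: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorised categorical draw: next[i] ~ P[current[i], :]."""
    cum = np.cumsum(P[current], axis=1)
    u = rng.random(len(current))
    return (u[:, None] > cum).sum(axis=1)


def simulate_alignment(tree: TimeTree, recipe: SimulationRecipe) -> Alignment:
    """Evolve ``n_sites`` independent sites down ``tree``.

    Each site draws a rate category, a root (or origin) state from the
    stationary frequencies of the oldest epoch present, and then evolves
    along every branch; crossing the epoch boundary applies one
    categorical draw from the saltation matrix row of the current state.
    """
    rng = np.random.default_rng(recipe.seed)
    basis, config = recipe.basis, recipe.config
    L = recipe.n_sites
    active = config.indicator > 0
    te = config.boundary_age
    cat_rates = recipe.site_model.rates
    k = len(cat_rates)
    site_cat = rng.integers(k, size=L)

    eig_f = EigenSystem(normalized_rate_matrix(basis), basis.frequencies)
    if active:
        red = reduce_alphabet(basis, config)
        eig_r = EigenSystem(normalized_rate_matrix(red.basis), red.basis.frequencies)
        Xi = saltation_matrix(basis, config).entries
        index_map = red.index_map
    top_height = tree.origin_height if tree.origin_height is not None else tree.heights[tree.root]
    freqs = root_frequencies(basis, config, top_height)
    top_reduced = active and top_height > te

    def evolve(states: np.ndarray, hp: float, hc: float, rate: float) -> np.ndarray:
        """Evolve site states from a node at hp down to a node at hc."""
        if active:
            tau2, tau1 = split_branch_at_boundary(hp, hc, te, rate)
        else:
            tau2, tau1 = 0.0, rate * (hp - hc)
        parent_reduced = active and hp > te
        child_reduced = active and hc > te
        out = states.copy()
        for c in range(k):
            idx = np.where(site_cat == c)[0]
            if idx.size == 0:
                continue
            s = out[idx]
            if parent_reduced:
                P2 = eig_r.probabilities(cat_rates[c] * tau2)
                s = _draw_states(P2, s, rng)
                if not child_reduced:
                    s = _draw_states(Xi, s, rng)  # saltation at the boundary
            if not child_reduced and tau1 >= 0:
                P1 = eig_f.probabilities(cat_rates[c] * tau1)
                s = _draw_states(P1, s, rng)
            out[idx] = s
        return out

    cum = np.cumsum(freqs)
    top_states = (rng.random(L)[:, None] > cum).sum(axis=1)
    node_states: dict[int, np.ndarray] = {}
    if tree.origin_height is not None:
        node_states[tree.root] = evolve(
            top_states, tree.origin_height, tree.heights[tree.root], recipe.clock.mean_rate
        )
    else:
        node_states[tree.root] = top_states

    for node in tree.postorder()[::-1]:  # preorder
        if node == tree.root:
            continue
        p = tree.parent[node]
        rate = recipe.clock.mean_rate * tree.branch_rates[node]
        node_states[node] = evolve(
            node_states[p], tree.heights[p], tree.heights[node], rate
        )

    seqs, taxa = [], []
    full_states = basis.alphabet.states
    for leaf in tree.leaves():
        s = node_states[leaf]
        if active and tree.heights[leaf] > te:
            # dated tip in the old epoch: emit full-alphabet labels; a
            # merged state emits either sub-state at its equilibrium ratio
            full = index_map[s]
            if config.indicator == 1:
                g0, g1 = config.discarded, config.retained
                pi = basis.frequencies
                p_g1 = pi[g1] / (pi[g1] + pi[g0])
                hit = full == g1
                flip = rng.random(hit.sum()) > p_g1
                sub = np.where(flip, g0, g1)
                full = full.copy()
                full[hit] = sub
            s = full
        taxa.append(tree.labels[leaf])
        seqs.append("".join(full_states[i] for i in s))
    return Alignment(tuple(taxa), tuple(seqs), basis.alphabet)


def sample_from_prior(priors, n_taxa: int, n_sites: int, seed: int):
    """Draw (parameters, tree, alignment) from the generative model.

    ``priors`` is a :class:`resub.mcmc.PriorSpec`.  Returns a dict of
    ground-truth parameter values, the simulated :class:`TimeTree`, and
    the simulated :class:`Alignment` — the inputs to one replicate of a
    calibration (coverage) study.
    """
    from .mcmc import PriorSpec  # deferred: mcmc imports this module

    assert isinstance(priors, PriorSpec)
    rng = np.random.default_rng(seed)
    truth = priors.draw(rng, n_taxa=n_taxa)
    tree = truth.pop("_tree")
    recipe = SimulationRecipe(
        basis=truth["_basis"],
        config=truth["_config"],
        site_model=truth["_site_model"],
        clock=truth["_clock"],
        n_sites=n_sites,
        seed=int(rng.integers(2**31)),
    )
    aln = simulate_alignment(tree, recipe)
    return truth, tree, aln
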