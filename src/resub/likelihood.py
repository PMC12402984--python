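"""Dated trees, alignments, and the epoch-aware pruning likelihood.

The likelihood p(D | T, theta) is computed by Felsenstein's pruning
algorithm, generalised to a two-epoch state space.  Partial-likelihood
vectors at nodes older than the boundary age ``te`` live in the reduced
(m-1)-state alphabet; nodes at or younger than ``te`` live in the full
m-state alphabet (the old epoch is the half-open interval (te, root], so
a node exactly at the boundary belongs to the young epoch).  A branch
that crosses the boundary contributes the rectangular matrix
``P'(tau2) @ Xi @ P(tau1)``.

Site-rate heterogeneity averages the per-category pattern likelihoods
with equal weights.  Per-node rescaling with accumulated log scalers
keeps deep alignments inside floating-point range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import ResubConfiguration, reduce_alphabet
from .substitution import (
    AMBIGUITY_SETS,
    Alphabet,
    EigenSystem,
    SiteRateModel,
    SubstitutionBasis,
    ValidationError,
    normalized_rate_matrix,
)

__all__ = [
    "TimeTree",
    "Alignment",
    "ClockModel",
    "split_branch_at_boundary",
    "pattern_compress",
    "tree_log_likelihood",
    "TreeLikelihood",
]

GAP_CODES = frozenset("-X?")


# ---------------------------------------------------------------------------
# data model


class TimeTree:
    """A rooted binary tree with node heights (time before present).

    Nodes are integers ``0 .. 2N-2``; leaves carry taxon labels.  Heights
    decrease from parent to child; extant leaves sit at height zero, and
    dated non-extant (serially sampled) leaves may sit above it.  An
    optional ``origin_height`` places a degree-one stem above the root.
    Per-branch rate multipliers (for relaxed clocks) default to one; the
    multiplier of node ``i`` applies to the branch above ``i``.
    """

    def __init__(
        self,
        parent: np.ndarray,
        heights: np.ndarray,
        labels: list[str | None],
        origin_height: float | None = None,
        branch_rates: np.ndarray | None = None,
    ):
        self.parent = np.asarray(parent, dtype=int)
        self.heights = np.asarray(heights, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.heights) == len(self.labels) == n):
            raise ValidationError("parent, heights and labels must have equal length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise ValidationError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        for i, ch in enumerate(self.children):
            if len(ch) not in (0, 2):
                raise ValidationError(f"tree must be binary; node {i} has {len(ch)} children")
            if ch and self.labels[i] is None:
                pass
        for i, p in enumerate(self.parent):
            if p >= 0 and self.heights[p] <= self.heights[i]:
                raise ValidationError(
                    f"parent height {self.heights[p]} not above child height {self.heights[i]} (node {i})"
                )
        if origin_height is not None and origin_height < self.heights[self.root]:
            raise ValidationError("origin height must be at or above the root height")
        self.origin_height = origin_height
        self.branch_rates = (
            np.ones(n) if branch_rates is None else np.asarray(branch_rates, dtype=float)
        )
        self._postorder: np.ndarray | None = None
        self._internal: np.ndarray | None = None

    # -- structure -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_leaves(self) -> int:
        return sum(1 for ch in self.children if not ch)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    def postorder(self) -> np.ndarray:
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:
                node = stack.pop()
                order.append(node)
                stack.extend(self.children[node])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    def internal_nodes(self) -> np.ndarray:
        if self._internal is None:
            self._internal = np.array(
                [i for i in range(self.n_nodes) if self.children[i]], dtype=int
            )
        return self._internal

    def taxon_node(self, label: str) -> int:
        for i in range(self.n_nodes):
            if self.labels[i] == label:
                return i
        raise KeyError(f"taxon {label!r} not in tree")

    def mrca(self, taxa) -> int:
        """Most recent common ancestor of a set of taxon labels."""
        nodes = {self.taxon_node(t) for t in taxa}
        paths = []
        for n in nodes:
            path = [n]
            while self.parent[path[-1]] >= 0:
                path.append(self.parent[path[-1]])
            paths.append(path)
        common = set(paths[0]).intersection(*map(set, paths[1:])) if len(paths) > 1 else set(paths[0])
        return min(common, key=lambda n: self.heights[n])

    def cherries(self) -> list[int]:
        """Internal nodes whose two children are both leaves."""
        return [
            i
            for i in range(self.n_nodes)
            if len(self.children[i]) == 2 and all(self.is_leaf(c) for c in self.children[i])
        ]

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        return all(abs(self.heights[i]) <= tol for i in self.leaves())

    def tree_length(self) -> float:
        """Total branch duration in time units (origin branch excluded)."""
        total = 0.0
        for i in range(self.n_nodes):
            if self.parent[i] >= 0:
                total += self.heights[self.parent[i]] - self.heights[i]
        return total

    def copy(self) -> "TimeTree":
        t = TimeTree(
            self.parent.copy(),
            self.heights.copy(),
            list(self.labels),
            self.origin_height,
            self.branch_rates.copy(),
        )
        return t

    def with_heights(self, heights: np.ndarray) -> "TimeTree":
        """Shallow clone sharing topology, with replaced node heights.

        Skips re-validation; callers must guarantee parent-above-child.
        Used on the sampler hot path.
        """
        t = object.__new__(TimeTree)
        t.parent = self.parent
        t.heights = np.asarray(heights, dtype=float)
        t.labels = self.labels
        t.children = self.children
        t.root = self.root
        t.origin_height = self.origin_height
        t.branch_rates = self.branch_rates
        t._postorder = self._postorder if self._postorder is not None else self.postorder()
        t._internal = self.internal_nodes()
        return t


@dataclass(frozen=True)
class Alignment:
    """Taxon-labelled sequences over an alphabet, with gaps and ambiguity.

    '-', 'X' and '?' are fully ambiguous; for the protein alphabet, 'B',
    'Z' and 'J' expand to their conventional two-state sets.
    """

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    alphabet: Alphabet

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(self.taxa))
        # normalise case only when the alphabet itself is upper-case
        # (toy alphabets may use lower-case letters as state labels)
        if all(s == s.upper() for s in self.alphabet.states):
            object.__setattr__(self, "sequences", tuple(s.upper() for s in self.sequences))
        else:
            object.__setattr__(self, "sequences", tuple(self.sequences))
        if len(self.taxa) != len(self.sequences):
            raise ValidationError("one sequence per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            dup = [t for t in self.taxa if self.taxa.count(t) > 1][0]
            raise ValidationError(f"duplicate taxon identifier {dup!r}")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError(f"sequences have unequal lengths {sorted(lengths)}")
        legal = set(self.alphabet.states) | GAP_CODES | {
            c for c, members in AMBIGUITY_SETS.items()
            if all(s in self.alphabet.states for s in members)
        }
        for taxon, seq in zip(self.taxa, self.sequences):
            bad = set(seq) - legal
            if bad:
                col = min(seq.index(c) for c in bad)
                raise ValidationError(
                    f"illegal residue {seq[col]!r} at column {col + 1} of sequence {taxon!r}"
                )

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def column(self, j: int) -> str:
        return "".join(s[j] for s in self.sequences)


@dataclass(frozen=True)
class ClockModel:
    """Molecular clock: strict, or uncorrelated-lognormal via branch multipliers.

    ``mean_rate`` is in substitutions per site per time unit.  Under the
    relaxed mode, per-branch multipliers live on the tree
    (``TimeTree.branch_rates``) and ``sigma`` is the stdev of their log.
    """

    mean_rate: float = 1.0
    mode: str = "strict"
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_rate <= 0:
            raise ValidationError("clock rate must be positive")
        if self.mode not in ("strict", "ucln"):
            raise ValidationError(f"unknown clock mode {self.mode!r}")


# ---------------------------------------------------------------------------
# operations


def split_branch_at_boundary(
    parent_height: float, child_height: float, te: float, rate: float
) -> tuple[float, float]:
    """Split a branch into old-epoch and young-epoch genetic distances.

    Returns ``(tau2, tau1)``: the distances accumulated above and below
    the boundary age ``te``, scaled by the clock ``rate``.  Their sum is
    always ``rate * (parent_height - child_height)``.
    """
    if parent_height < child_height:
        raise ValueError(
            f"parent height {parent_height} below child height {child_height}"
        )
    if rate <= 0:
        raise ValueError("rate must be positive")
    tau1 = rate * max(0.0, min(te, parent_height) - child_height)
    tau2 = rate * (parent_height - child_height) - tau1
    return max(tau2, 0.0), tau1


def pattern_compress(aln: Alignment) -> tuple[np.ndarray, np.ndarray]:
    """Collapse an alignment to its unique site patterns and their counts.

    Returns ``(patterns, weights)`` where ``patterns`` is an array of
    shape ``(n_patterns, n_taxa)`` of single characters (rows ordered by
    first occurrence) and ``weights`` counts occurrences of each pattern.
    """
    cols = np.array([list(s) for s in aln.sequences]).T  # (L, N)
    if cols.size == 0:
        return np.empty((0, aln.n_taxa), dtype="<U1"), np.empty(0, dtype=int)
    uniq, first, counts = np.unique(cols, axis=0, return_index=True, return_counts=True)
    order = np.argsort(first)
    return uniq[order], counts[order]


def _leaf_partial(char: str, alphabet: Alphabet) -> np.ndarray:
    v = np.zeros(alphabet.size)
    if char in alphabet.states:  # state labels take precedence over codes
        v[alphabet.index(char)] = 1.0
    elif char in GAP_CODES:
        v[:] = 1.0
    elif char in AMBIGUITY_SETS:
        for s in AMBIGUITY_SETS[char]:
            v[alphabet.index(s)] = 1.0
    else:
        v[alphabet.index(char)] = 1.0
    return v


class TreeLikelihood:
    """Reusable epoch-aware pruning engine for one alignment and topology.

    Pattern compression, leaf partials and the spectral decompositions of
    the per-epoch rate matrices are cached; heights, boundary age,
    saltation fraction, site-rate shape and clock rate can change between
    calls at no set-up cost.  Call :meth:`set_basis` after changing
    exchangeabilities or frequencies.
    """

    def __init__(
        self,
        tree: TimeTree,
        aln: Alignment,
        basis: SubstitutionBasis,
        config: ResubConfiguration,
        site_model: SiteRateModel,
        clock: ClockModel,
    ):
        missing = set(t for t in (tree.labels[i] for i in tree.leaves())) ^ set(aln.taxa)
        if missing:
            raise ValidationError(f"taxa do not match between tree and alignment: {sorted(missing)}")
        if basis.alphabet.states != aln.alphabet.states:
            raise ValidationError("alignment and substitution model use different alphabets")
        self.tree = tree
        self.aln = aln
        self.config = config
        self.site_model = site_model
        self.clock = clock
        patterns, weights = pattern_compress(aln)
        self.weights = weights.astype(float)
        self.n_patterns = len(weights)
        taxon_row = {t: k for k, t in enumerate(aln.taxa)}
        self._leaf_partials: dict[int, np.ndarray] = {}
        for leaf in tree.leaves():
            row = taxon_row[tree.labels[leaf]]
            self._leaf_partials[leaf] = np.array(
                [_leaf_partial(c, basis.alphabet) for c in patterns[:, row]]
            )  # (P, m)
        self.set_basis(basis)

    def set_basis(self, basis: SubstitutionBasis) -> None:
        self.basis = basis
        self._eigen_full = EigenSystem(normalized_rate_matrix(basis), basis.frequencies)
        self._eigen_reduced: dict[tuple, EigenSystem] = {}
        self._reduced_map: dict[tuple, np.ndarray] = {}

    def _reduced(self, config: ResubConfiguration) -> tuple[EigenSystem, np.ndarray]:
        key = (config.indicator, config.alpha, config.beta)
        if key not in self._eigen_reduced:
            red = reduce_alphabet(self.basis, config)
            self._eigen_reduced[key] = EigenSystem(
                normalized_rate_matrix(red.basis), red.basis.frequencies
            )
            self._reduced_map[key] = red.index_map
        return self._eigen_reduced[key], self._reduced_map[key]

    def _xi(self, config: ResubConfiguration, red_map: np.ndarray) -> np.ndarray:
        """Saltation entries without validation overhead (hot path)."""
        pi = self.basis.frequencies
        m = self.basis.size
        g1, g0 = config.retained, config.discarded
        nu = config.saltation_fraction
        X = np.zeros((m - 1, m))
        rows = np.arange(m - 1)
        X[rows, red_map] = 1.0 - pi[g0] if config.indicator > 1 else 1.0 - pi[g0] - pi[g1]
        X[:, g0] = pi[g0]
        if config.indicator == 1:
            X[:, g1] = np.where(red_map == g1, X[:, g1], pi[g1])
        slot = int(np.where(red_map == g1)[0][0])
        X[slot, :] = 0.0
        X[slot, g0] = nu
        X[slot, g1] = 1.0 - nu
        return X

    def log_likelihood(
        self,
        tree: TimeTree | None = None,
        config: ResubConfiguration | None = None,
        site_model: SiteRateModel | None = None,
        clock: ClockModel | None = None,
    ) -> float:
        tree = tree if tree is not None else self.tree
        config = config if config is not None else self.config
        site_model = site_model if site_model is not None else self.site_model
        clock = clock if clock is not None else self.clock

        cat = site_model.rates  # (k,)
        k = len(cat)
        h = tree.heights
        te = config.boundary_age
        active = config.indicator > 0
        eig_f = self._eigen_full
        eig_r, red_map = self._reduced(config) if active else (None, None)
        Xi = self._xi(config, red_map) if active else None
        m = self.basis.size

        def to_reduced(L: np.ndarray) -> np.ndarray:
            """Project a full-alphabet leaf partial into the reduced space.

            Under refinement the merged slot accepts either sub-state
            (elementwise max); an observation of the discarded state under
            expansion has no reduced-space support and zeroes out.
            """
            out = L[..., red_map].copy()
            if config.indicator == 1:
                g0, g1 = config.discarded, config.retained
                slot = int(np.where(red_map == g1)[0][0])
                out[..., slot] = np.maximum(L[..., g1], L[..., g0])
            return out

        partials: dict[int, np.ndarray] = {}  # node -> (k, P, dim)
        logscale = np.zeros((k, self.n_patterns))

        # ---- batch: per-branch epoch splits, then all P factors at once
        n = tree.n_nodes
        has_origin = tree.origin_height is not None
        nb = n + (1 if has_origin else 0)  # branch index == child node; last = stem
        tau1 = np.zeros(nb)
        tau2 = np.zeros(nb)
        hp_arr = np.zeros(nb)
        hc_arr = np.zeros(nb)
        for b in range(nb):
            if b < n:
                p = tree.parent[b]
                if p < 0:
                    continue
                hp_arr[b], hc_arr[b] = h[p], h[b]
                rate = clock.mean_rate * tree.branch_rates[b]
            else:
                hp_arr[b], hc_arr[b] = tree.origin_height, h[tree.root]
                rate = clock.mean_rate
            if active:
                tau2[b], tau1[b] = split_branch_at_boundary(hp_arr[b], hc_arr[b], te, rate)
            else:
                tau1[b] = rate * (hp_arr[b] - hc_arr[b])
        parent_red = active & (hp_arr > te)
        child_red = active & (hc_arr > te)
        Pf = eig_f.probabilities(np.multiply.outer(tau1, cat))  # (nb, k, m, m)
        Pr = eig_r.probabilities(np.multiply.outer(tau2, cat)) if active else None

        def branch_message(b: int, child: int) -> np.ndarray:
            # message[c,p,i] = sum_j P[c,i,j] * Lc[c,p,j], batched over
            # rate categories c via BLAS matmul
            Lc = partials[child]
            if child_red[b]:
                # branch wholly in the old epoch (tau1 is zero here)
                if Lc.shape[-1] == m:  # serially sampled leaf above the boundary
                    Lc = to_reduced(Lc)
                return Lc @ Pr[b].transpose(0, 2, 1)
            M = Lc @ Pf[b].transpose(0, 2, 1)
            if parent_red[b]:
                M = M @ Xi.T
                M = M @ Pr[b].transpose(0, 2, 1)
            return M

        for node in tree.postorder():
            if tree.is_leaf(node):
                partials[node] = np.broadcast_to(
                    self._leaf_partials[node], (k,) + self._leaf_partials[node].shape
                )
                continue
            msgs = [branch_message(c, c) for c in tree.children[node]]
            L = msgs[0] * msgs[1]
            scale = L.max(axis=2)  # (k, P)
            safe = np.where(scale > 0, scale, 1.0)
            partials[node] = L / safe[:, :, None]
            with np.errstate(divide="ignore"):
                logscale += np.where(scale > 0, np.log(safe), -np.inf)

        top = partials[tree.root]
        top_height = tree.heights[tree.root]
        if has_origin:
            top = branch_message(nb - 1, tree.root)  # stem branch
            top_height = tree.origin_height
        # equals root_frequencies(basis, config, top_height), via the caches
        freqs = eig_r.pi if (active and top_height > te) else self.basis.frequencies
        site = top @ freqs  # (k, P)

        with np.errstate(divide="ignore"):
            log_site = np.log(site) + logscale
        # equal-weight average over rate categories, in log space
        mx = log_site.max(axis=0)
        finite = np.isfinite(mx)
        out = np.full(self.n_patterns, -np.inf)
        out[finite] = mx[finite] + np.log(
            np.exp(log_site[:, finite] - mx[finite]).mean(axis=0)
        )
        return float(self.weights @ out)


def tree_log_likelihood(
    tree: TimeTree,
    aln: Alignment,
    basis: SubstitutionBasis,
    config: ResubConfiguration,
    site_model: SiteRateModel | None = None,
    clock: ClockModel | None = None,
) -> float:
    """log p(D | T, theta) under the two-epoch substitution model.

    One-shot convenience wrapper over :class:`TreeLikelihood`.
    """
    if site_model is None:
        site_model = SiteRateModel(1.0, 1, np.array([1.0]))
    if clock is None:
        clock = ClockModel()
    engine = TreeLikelihood(tree, aln, basis, config, site_model, clock)
    return engine.log_likelihood()
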