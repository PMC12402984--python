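"""Tree/alignment data model and the epoch-aware pruning likelihood."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from resub import (
    Alignment,
    Alphabet,
    ClockModel,
    ResubConfiguration,
    SiteRateModel,
    SubstitutionBasis,
    TimeTree,
    ValidationError,
    discrete_gamma_rates,
    normalized_rate_matrix,
    pattern_compress,
    protein_alphabet,
    transition_matrix,
    tree_log_likelihood,
)
from conftest import random_basis


class TestTimeTree:
    def test_structure_and_queries(self):
        tree = TimeTree(
            parent=[3, 3, 4, 4, -1],
            heights=[0, 0, 0, 0.5, 1.2],
            labels=["A", "B", "C", None, None],
        )
        assert tree.root == 4
        assert tree.n_leaves == 3
        assert tree.is_ultrametric()
        assert tree.mrca(["A", "B"]) == 3
        assert tree.mrca(["A", "C"]) == 4
        assert tree.cherries() == [3]
        assert np.isclose(tree.tree_length(), 0.5 + 0.5 + 1.2 + 0.7)

    def test_invalid_trees_rejected(self):
        with pytest.raises(ValidationError, match="parent height"):
            TimeTree(parent=[2, 2, -1], heights=[0.6, 0.0, 0.5],
                     labels=["A", "B", None])
        with pytest.raises(ValidationError, match="binary"):
            TimeTree(
                parent=[3, 3, 3, -1], heights=[0, 0, 0, 1], labels=["A", "B", "C", None]
            )

    def test_origin_below_root_rejected(self):
        with pytest.raises(ValidationError, match="origin"):
            TimeTree(
                parent=[2, 2, -1], heights=[0, 0, 1.0], labels=["A", "B", None],
                origin_height=0.5,
            )


class TestSplitBranch:
    def test_boundary_inside_branch(self):
        from resub import split_branch_at_boundary

        assert split_branch_at_boundary(1.0, 0.0, 0.5, 1.0) == (0.5, 0.5)

    def test_branch_fully_young(self):
        from resub import split_branch_at_boundary

        assert split_branch_at_boundary(0.4, 0.0, 0.5, 1.0) == (0.0, 0.4)

    def test_rate_scaling_and_conservation(self):
        from resub import split_branch_at_boundary

        assert split_branch_at_boundary(1.0, 0.0, 0.5, 2.0) == (1.0, 1.0)
        for te in (0.0, 0.2, 0.7, 1.5):
            t2, t1 = split_branch_at_boundary(1.2, 0.3, te, 1.7)
            assert np.isclose(t2 + t1, 1.7 * 0.9)

    def test_inverted_heights_rejected(self):
        from resub import split_branch_at_boundary

        with pytest.raises(ValueError):
            split_branch_at_boundary(0.1, 0.5, 0.3, 1.0)


class TestPatternCompress:
    def test_identical_columns(self, toy_alphabet):
        aln = Alignment(("A", "B"), ("xxxx", "WWWW"), toy_alphabet)
        patterns, weights = pattern_compress(aln)
        assert patterns.shape == (1, 2)
        assert weights.tolist() == [4]

    def test_distinct_columns(self, toy_alphabet):
        aln = Alignment(("A", "B"), ("xWY", "YWx"), toy_alphabet)
        patterns, weights = pattern_compress(aln)
        assert len(weights) == 3
        assert weights.tolist() == [1, 1, 1]

    def test_recomposition_matches_direct(self, toy_basis, toy_config, toy_alphabet):
        rng = np.random.default_rng(5)
        tree = TimeTree(
            parent=[3, 3, 4, 4, -1], heights=[0, 0, 0, 0.4, 0.9],
            labels=["A", "B", "C", None, None],
        )
        chars = np.array(list(toy_alphabet.states))
        seqs = ["".join(rng.choice(chars, 30)) for _ in range(3)]
        aln = Alignment(("A", "B", "C"), tuple(seqs), toy_alphabet)
        total = tree_log_likelihood(tree, aln, toy_basis, toy_config)
        direct = sum(
            tree_log_likelihood(
                tree,
                Alignment(("A", "B", "C"), tuple(s[j] for s in seqs), toy_alphabet),
                toy_basis,
                toy_config,
            )
            for j in range(30)
        )
        assert np.isclose(total, direct, atol=1e-12 * 30)


class TestTreeLikelihood:
    def test_one_taxon_patterns(self, one_taxon_tree, toy_basis, toy_alphabet):
        """Fixed alphabet: pattern probability is (pi . P(rate*1))[state]."""
        cfg = ResubConfiguration(1, 2, indicator=0)
        q = normalized_rate_matrix(toy_basis)
        P = transition_matrix(q, 1.0).entries
        expected = toy_basis.frequencies @ P
        total = 0.0
        for i, c in enumerate(toy_alphabet.states):
            ll = tree_log_likelihood(
                one_taxon_tree, Alignment(("A",), (c,), toy_alphabet), toy_basis, cfg
            )
            assert np.isclose(np.exp(ll), expected[i], atol=1e-12)
            total += np.exp(ll)
        assert np.isclose(total, 1.0, atol=1e-12)

    def test_null_matches_textbook_pruning(self, toy_basis, toy_alphabet):
        """Is=0 equals an independent standard pruning implementation."""
        rng = np.random.default_rng(9)
        tree = TimeTree(
            parent=[5, 5, 6, 7, 7, 6, 8, 8, -1],
            heights=[0, 0, 0, 0, 0, 0.3, 0.8, 0.45, 1.4],
            labels=["A", "B", "C", "D", "E", None, None, None, None],
        )
        chars = np.array(list(toy_alphabet.states))
        seqs = tuple("".join(rng.choice(chars, 12)) for _ in range(5))
        aln = Alignment(("A", "B", "C", "D", "E"), seqs, toy_alphabet)
        cfg = ResubConfiguration(1, 2, indicator=0)
        ll = tree_log_likelihood(tree, aln, toy_basis, cfg)

        # oracle: naive recursive pruning with scipy expm, no sharing
        q = normalized_rate_matrix(toy_basis).entries
        taxon_row = {t: i for i, t in enumerate(aln.taxa)}

        def partial(node, site):
            if tree.is_leaf(node):
                v = np.zeros(3)
                v[toy_alphabet.index(seqs[taxon_row[tree.labels[node]]][site])] = 1
                return v
            out = np.ones(3)
            for c in tree.children[node]:
                P = expm(q * (tree.heights[node] - tree.heights[c]))
                out *= P @ partial(c, site)
            return out

        oracle = sum(
            np.log(toy_basis.frequencies @ partial(tree.root, s)) for s in range(12)
        )
        assert np.isclose(ll, oracle, atol=1e-10)

    def test_null_invariant_to_boundary_parameters(
        self, two_taxon_tree, toy_basis, toy_alphabet
    ):
        aln = Alignment(("A", "B"), ("x", "Y"), toy_alphabet)
        ref = tree_log_likelihood(
            two_taxon_tree, aln, toy_basis, ResubConfiguration(1, 2, indicator=0)
        )
        for te in (0.1, 0.6, 2.0):
            for nu in (0.0, 0.5, 1.0):
                cfg = ResubConfiguration(
                    1, 2, indicator=0, boundary_age=te, saltation_fraction=nu
                )
                assert tree_log_likelihood(two_taxon_tree, aln, toy_basis, cfg) == ref

    @pytest.mark.parametrize("indicator", [0, 1, 2, 3])
    def test_total_probability_three_taxa(self, toy_basis, toy_alphabet, indicator):
        """Pattern probabilities sum to one across the boundary bookkeeping."""
        tree = TimeTree(
            parent=[3, 3, 4, 4, -1], heights=[0, 0, 0, 0.4, 0.9],
            labels=["A", "B", "C", None, None],
        )
        for te in (0.2, 0.4, 0.65, 0.9, 1.4):
            cfg = ResubConfiguration(
                1, 2, indicator=indicator, boundary_age=te, saltation_fraction=0.35
            )
            total = sum(
                np.exp(
                    tree_log_likelihood(
                        tree,
                        Alignment(("A", "B", "C"), pat, toy_alphabet),
                        toy_basis,
                        cfg,
                        discrete_gamma_rates(0.8, 3),
                    )
                )
                for pat in itertools.product(toy_alphabet.states, repeat=3)
            )
            assert np.isclose(total, 1.0, atol=1e-9), (indicator, te)

    def test_boundary_discontinuity_at_root(
        self, two_taxon_tree, toy_basis, toy_alphabet
    ):
        """Site likelihoods jump when te crosses the root height (0.5)."""
        aln = Alignment(("A", "B"), ("W", "W"), toy_alphabet)

        def ll(te):
            cfg = ResubConfiguration(
                1, 2, indicator=3, boundary_age=te, saltation_fraction=0.25
            )
            return tree_log_likelihood(two_taxon_tree, aln, toy_basis, cfg)

        eps = 1e-7
        below, above = ll(0.5 - eps), ll(0.5 + eps)
        assert abs(below - above) > 1e-3  # genuine jump
        # continuity away from node heights
        assert abs(ll(0.3) - ll(0.3 + eps)) < 1e-5

    def test_gap_column_is_marginalised(self, two_taxon_tree, toy_basis, toy_alphabet):
        cfg = ResubConfiguration(1, 2, indicator=3, boundary_age=0.6,
                                 saltation_fraction=0.2)
        for gap in ("-", "X", "?"):
            ll = tree_log_likelihood(
                two_taxon_tree,
                Alignment(("A", "B"), (gap.replace("X", "-"), gap), toy_alphabet),
                toy_basis,
                cfg,
            )
            assert np.isclose(np.exp(ll), 1.0, atol=1e-12)
        mix = tree_log_likelihood(
            two_taxon_tree, Alignment(("A", "B"), ("x", "-"), toy_alphabet),
            toy_basis, cfg,
        )
        marginal = sum(
            np.exp(
                tree_log_likelihood(
                    two_taxon_tree,
                    Alignment(("A", "B"), ("x", c), toy_alphabet),
                    toy_basis,
                    cfg,
                )
            )
            for c in toy_alphabet.states
        )
        assert np.isclose(np.exp(mix), marginal, atol=1e-12)

    def test_protein_ambiguity_codes(self):
        ab = protein_alphabet()
        rng = np.random.default_rng(2)
        basis = random_basis(rng, 20)
        basis = SubstitutionBasis(ab, basis.exchangeabilities, basis.frequencies)
        tree = TimeTree(parent=[2, 2, -1], heights=[0, 0, 0.7],
                        labels=["A", "B", None])
        cfg = ResubConfiguration(ab.index("W"), ab.index("Y"), indicator=0)
        b_code = tree_log_likelihood(tree, Alignment(("A", "B"), ("A", "B"), ab),
                                     basis, cfg)
        explicit = sum(
            np.exp(tree_log_likelihood(tree, Alignment(("A", "B"), ("A", c), ab),
                                       basis, cfg))
            for c in ("D", "N")
        )
        assert np.isclose(np.exp(b_code), explicit, atol=1e-14)

    def test_taxon_mismatch_rejected(self, two_taxon_tree, toy_basis, toy_alphabet):
        aln = Alignment(("A", "Z"), ("x", "x"), toy_alphabet)
        with pytest.raises(ValidationError, match="taxa"):
            tree_log_likelihood(
                two_taxon_tree, aln, toy_basis, ResubConfiguration(1, 2)
            )

    def test_rescaling_handles_deep_alignments(self, toy_basis, toy_alphabet):
        """Many sites on a tall tree stay finite through log-scaler rescaling."""
        tree = TimeTree(
            parent=[3, 3, 4, 4, -1], heights=[0, 0, 0, 2.0, 40.0],
            labels=["A", "B", "C", None, None],
        )
        rng = np.random.default_rng(1)
        chars = np.array(list(toy_alphabet.states))
        seqs = tuple("".join(rng.choice(chars, 500)) for _ in range(3))
        cfg = ResubConfiguration(1, 2, indicator=1, boundary_age=5.0,
                                 saltation_fraction=0.5)
        ll = tree_log_likelihood(
            tree, Alignment(("A", "B", "C"), seqs, toy_alphabet), toy_basis, cfg
        )
        assert np.isfinite(ll)


class TestAlignment:
    def test_duplicate_taxa_rejected(self, toy_alphabet):
        with pytest.raises(ValidationError, match="duplicate"):
            Alignment(("A", "A"), ("x", "Y"), toy_alphabet)

    def test_unequal_lengths_rejected(self, toy_alphabet):
        with pytest.raises(ValidationError, match="length"):
            Alignment(("A", "B"), ("xx", "x"), toy_alphabet)

    def test_illegal_residue_located(self):
        with pytest.raises(ValidationError, match="column 3"):
            Alignment(("A", "B"), ("ACDE", "AC0E"), protein_alphabet())

    def test_case_normalisation_protein_only(self, toy_alphabet):
        prot = Alignment(("A",), ("acd",), protein_alphabet())
        assert prot.sequences == ("ACD",)
        toy = Alignment(("A",), ("xWY",), toy_alphabet)
        assert toy.sequences == ("xWY",)
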