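"""Priors, Metropolis-Hastings sampling, model support and diagnostics."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from resub import (
    BirthDeathParams,
    Calibration,
    MCMCSettings,
    ModelState,
    PriorSpec,
    SubstitutionBasis,
    TABLE_CALIBRATIONS,
    ValidationError,
    classify_support,
    cross_brace_log_prior,
    effective_sample_size,
    log_prior,
    mcmc,
    model_support,
    run_chains,
    sample_from_prior,
    simulate_bd_tree,
)
from resub.mcmc import _lognormal_logpdf
from conftest import random_basis


@pytest.fixture
def toy_priors(toy_alphabet):
    return PriorSpec(
        alphabet=toy_alphabet, cherry=("W", "Y"),
        fixed_clock_rate=1.0, fixed_shape=1.0,
    )


def make_state(tree, basis, te=None, nu=0.5, indicator=0):
    return ModelState(
        heights=tree.heights.copy(),
        te=float(tree.heights[tree.root]) if te is None else te,
        nu=nu,
        indicator=indicator,
        pi=basis.frequencies.copy(),
        r=basis.exchangeabilities.copy(),
        shape=1.0,
        clock_rate=1.0,
    )


class TestLogPrior:
    def test_laplace_term_at_mode(self, toy_basis, toy_priors):
        tree = simulate_bd_tree(toy_priors.bd, 5, seed=1)
        anchor = tree.cherries()[0]
        s1 = make_state(tree, toy_basis, te=float(tree.heights[anchor]))
        s2 = make_state(tree, toy_basis, te=float(tree.heights[anchor]) + toy_priors.delta)
        lp1 = log_prior(s1, tree, toy_priors, anchor)
        lp2 = log_prior(s2, tree, toy_priors, anchor)
        # Laplace log density falls by exactly 1 at one scale from the mode
        assert np.isclose(lp1 - lp2, 1.0, atol=1e-12)

    def test_out_of_support_is_minus_inf(self, toy_basis, toy_priors):
        tree = simulate_bd_tree(toy_priors.bd, 5, seed=1)
        anchor = tree.cherries()[0]
        s = make_state(tree, toy_basis, nu=1.5)
        assert log_prior(s, tree, toy_priors, anchor) == -np.inf
        s = make_state(tree, toy_basis, te=-0.01)
        assert log_prior(s, tree, toy_priors, anchor) == -np.inf
        s = make_state(tree, toy_basis)
        s.heights[tree.root] = -1.0
        assert log_prior(s, tree, toy_priors, anchor) == -np.inf

    def test_calibration_density_is_quadrature_checked_lognormal(self):
        """LUCA age prior: LogNormal with real-space mean 4.25 and sd 0.0094."""
        mean, sd = TABLE_CALIBRATIONS["LUCA"]
        # density integrates to 1 and matches scipy's lognorm parameterisation
        total, _ = quad(lambda x: np.exp(_lognormal_logpdf(x, mean, sd)), 4.1, 4.4)
        assert np.isclose(total, 1.0, atol=1e-8)
        sigma = np.sqrt(np.log1p((sd / mean) ** 2))
        ref = stats.lognorm(s=sigma, scale=mean * np.exp(-sigma**2 / 2))
        for x in (4.24, 4.25, 4.26):
            assert np.isclose(_lognormal_logpdf(x, mean, sd), ref.logpdf(x), atol=1e-10)
        # the moments really are (mean, sd)
        m1, _ = quad(lambda x: x * np.exp(_lognormal_logpdf(x, mean, sd)), 4.1, 4.4)
        assert np.isclose(m1, mean, atol=1e-6)


class TestCrossBrace:
    def test_identical_heights(self):
        val = cross_brace_log_prior([4.0, 3.0], [4.0, 3.0], mean=0.01)
        assert np.isclose(val, 2 * np.log(100.0), atol=1e-12)

    def test_root_offset_one_mean(self):
        val = cross_brace_log_prior([4.01, 3.0], [4.0, 3.0], mean=0.01)
        assert np.isclose(val, np.log(100.0) - 1.0 + np.log(100.0), atol=1e-12)

    def test_monotone_decreasing_in_difference(self):
        vals = [
            cross_brace_log_prior([4.0 + d, 3.0 + d], [4.0, 3.0]) for d in
            (0.0, 0.005, 0.02, 0.1)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValidationError):
            cross_brace_log_prior([4.0, 3.0], [4.0])


class TestClassifySupport:
    def test_strong_support(self):
        assert classify_support(0.95, 1.0) == "resub"  # BF = 19

    def test_boundary_is_ambiguous(self):
        assert classify_support(10 / 11, 1.0) == "?"  # BF = 10 exactly

    def test_even_posterior(self):
        assert classify_support(0.5, 1.0) == "?"

    def test_strong_rejection_and_extremes(self):
        assert classify_support(0.01, 1.0) == "no resub"
        assert classify_support(1.0, 1.0) == "resub"
        assert classify_support(0.0, 1.0) == "no resub"

    def test_prior_odds_divided_out(self):
        # posterior 0.95 is only BF ~6.3 against 3:1 prior odds
        assert classify_support(0.95, 3.0) == "?"


class TestEffectiveSampleSize:
    def test_iid_series(self):
        x = np.random.default_rng(0).normal(size=10_000)
        ess = effective_sample_size(x)
        assert abs(ess - 10_000) < 1500

    def test_ar1_closed_form(self):
        phi = 0.9
        rng = np.random.default_rng(1)
        n = 10_000
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + rng.normal()
        expected = n * (1 - phi) / (1 + phi)
        assert abs(effective_sample_size(x) - expected) < 0.25 * expected

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        phi = 0.8
        x = np.zeros(5000)
        for i in range(1, len(x)):
            x[i] = phi * x[i - 1] + rng.normal()
        mine = effective_sample_size(x)
        theirs = float(az.ess(x[None, :]))
        assert abs(mine - theirs) / theirs < 0.35

    def test_duplication_reduces_ess(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=4000)
        dup = np.repeat(x[:2000], 2)
        assert effective_sample_size(dup) < 0.75 * effective_sample_size(x)

    def test_constant_series(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert effective_sample_size(np.ones(100)) == 0.0
        assert any("constant" in str(w.message) for w in caught)

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            effective_sample_size([1.0, 2.0])


class TestModelSupport:
    def _trace(self, indicators):
        import pandas as pd

        from resub import PosteriorTrace

        df = pd.DataFrame({"Sample": range(len(indicators)), "Is": indicators})
        return PosteriorTrace(df, thin=1)

    def test_single_model(self):
        support = model_support(self._trace([0] * 50), burnin_fraction=0.0)
        assert support.tolist() == [1.0, 0.0, 0.0, 0.0]

    def test_counts(self):
        inds = [0] * 10 + [1] * 30 + [2] * 40 + [3] * 20
        support = model_support(self._trace(inds), burnin_fraction=0.0)
        assert np.allclose(support, [0.1, 0.3, 0.4, 0.2])

    def test_empty_trace_rejected(self):
        with pytest.raises(ValidationError):
            model_support(self._trace([]), burnin_fraction=0.0)


class TestMCMC:
    def test_seed_reproducibility(self, toy_basis, toy_priors):
        truth, tree, aln = sample_from_prior(toy_priors, 5, 30, seed=4)
        settings = MCMCSettings(chain_length=500, thin=10, seed=9)
        from dataclasses import replace

        pri = replace(toy_priors, fixed_basis=truth["_basis"],
                      anchor_taxa=truth["anchor_taxa"])
        t1 = mcmc(aln, tree, truth["_basis"], pri, settings)
        t2 = mcmc(aln, tree, truth["_basis"], pri, settings)
        assert t1.data.equals(t2.data)

    def test_two_chains_agree_on_support(self, toy_priors):
        from dataclasses import replace

        truth, tree, aln = sample_from_prior(toy_priors, 8, 120, seed=6)
        pri = replace(toy_priors, fixed_basis=truth["_basis"],
                      anchor_taxa=truth["anchor_taxa"])
        settings = MCMCSettings(chain_length=4000, thin=4, seed=1)
        traces = run_chains(2, aln, tree, truth["_basis"], pri, settings=settings)
        p = [float(model_support(t)[1:].sum()) for t in traces]
        assert abs(p[0] - p[1]) < 0.1

    def test_null_truth_rarely_supports_resub(self, toy_priors):
        """Data from the fixed-alphabet model should not be classified as
        two-alphabet (Bayes factor 10) in most replicates."""
        from dataclasses import replace

        hits = 0
        n_rep = 4
        for seed in range(n_rep):
            gen = replace(toy_priors, indicator_probs=(1.0, 0.0, 0.0, 0.0))
            truth, tree, aln = sample_from_prior(gen, 10, 150, seed=100 + seed)
            pri = replace(toy_priors, fixed_basis=truth["_basis"],
                          anchor_taxa=truth["anchor_taxa"])
            trace = mcmc(aln, tree, truth["_basis"], pri,
                         MCMCSettings(chain_length=3000, thin=4, seed=seed))
            p = float(model_support(trace)[1:].sum())
            if classify_support(p, prior_odds=3.0) == "resub":
                hits += 1
        assert hits == 0

    def test_estimating_frequencies_and_rates(self, toy_priors, toy_alphabet):
        """Full estimation of pi and r mixes and stays in support."""
        from dataclasses import replace

        truth, tree, aln = sample_from_prior(toy_priors, 6, 80, seed=12)
        pri = replace(toy_priors, fixed_basis=None, anchor_taxa=truth["anchor_taxa"])
        settings = MCMCSettings(
            chain_length=1500, thin=5, seed=2,
            estimate_frequencies=True, estimate_exchangeabilities=True,
            estimate_shape=True,
        )
        trace = mcmc(aln, tree, truth["_basis"], pri, settings)
        assert np.all(np.isfinite(trace.data["posterior"]))
        assert trace.acceptance["pi"] > 0
        assert trace.acceptance["r"] > 0

    def test_tree_log_matches_trace(self, toy_basis, toy_priors):
        """With tree logging on, one dated Newick is emitted per sample
        and its root age equals the trace's rootHeight column."""
        from resub import read_newick_dated, simulate_bd_tree

        tree = simulate_bd_tree(toy_priors.bd, 5, seed=8)
        settings = MCMCSettings(chain_length=200, thin=20, seed=3, log_trees=True)
        trace = mcmc(None, tree, toy_basis, toy_priors, settings)
        assert len(trace.trees) == len(trace.data)
        assert all(t.endswith(";") for t in trace.trees)
        last = trace.trees[-1]
        import tempfile, pathlib

        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "t.nwk"
            p.write_text(last + "\n")
            parsed = read_newick_dated(p)
        assert np.isclose(
            parsed.heights[parsed.root], trace.data["rootHeight"].iloc[-1], atol=1e-9
        )

    def test_topology_moves_preserve_validity(self, toy_priors):
        from dataclasses import replace

        truth, tree, aln = sample_from_prior(toy_priors, 8, 40, seed=3)
        pri = replace(toy_priors, fixed_basis=truth["_basis"],
                      anchor_taxa=truth["anchor_taxa"])
        settings = MCMCSettings(chain_length=1000, thin=10, seed=4,
                                estimate_topology=True)
        trace = mcmc(aln, tree, truth["_basis"], pri, settings)
        assert np.all(np.isfinite(trace.data["posterior"]))
        assert trace.acceptance["exchange"] >= 0
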