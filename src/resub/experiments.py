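"""Simulation-study harnesses and the BLOSUM cherry-score utility.

Three validation experiments accompany the model:

* **coverage** — well-calibrated Bayes check: parameters and trees are
  drawn from the prior, data simulated, and the posterior re-estimated;
  95% credible intervals should cover truth for ~95% of replicates.
* **model recovery** — data are simulated under the null and under the
  two-alphabet model; the indicator's posterior support is classified at
  a Bayes factor of 10 and the confusion table reported.
* **age bias** — data are simulated under the two-alphabet model and the
  tree height and old-epoch duration are re-estimated both under the
  (misspecified) fixed-alphabet null and under the two-alphabet model,
  quantifying the systematic age overestimation of the null.

All harnesses run at deliberately reduced sizes by default (taxon
counts, site counts, replicate counts and chain lengths chosen to keep a
complete study on a single CPU within minutes); the keyword arguments
scale every dimension up to full-size studies.

In each replicate the exchangeability matrix, frequencies, site-rate
shape and clock rate are drawn from their priors and then *conditioned
on* (held at truth) during inference, so the estimated quantities are
the epoch parameters (Is, te, nu) and the time-tree itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mcmc import (
    Calibration,
    MCMCSettings,
    PriorSpec,
    classify_support,
    effective_sample_size,
    mcmc,
    model_support,
)
from .simulate import sample_from_prior
from .substitution import ValidationError

__all__ = [
    "ExperimentReport",
    "blosum_cherry_score",
    "coverage_experiment",
    "model_recovery_experiment",
    "age_bias_experiment",
    "AARS_CHERRIES",
    "FALSE_CHERRIES",
]

#: The nine amino acid pairs whose synthetase families form cherries on
#: the Class I and II aaRS phylogenies.
AARS_CHERRIES = ("WY", "IV", "EQ", "AG", "SG", "PT", "FH", "DN", "DK")
#: Negative-control pairs spanning the two classes (not cherries).
FALSE_CHERRIES = ("LS", "CF", "NQ", "DE", "FY")


def blosum_cherry_score(pairs, matrix=None) -> float:
    """Mean pairwise substitution score of a set of amino acid pairs.

    ``pairs`` is an iterable of two-letter strings (or 2-tuples); the
    score matrix defaults to BLOSUM62.
    """
    from .io import blosum62

    pairs = list(pairs)
    if not pairs:
        raise ValidationError("need at least one amino acid pair")
    matrix = matrix if matrix is not None else blosum62()
    total = 0.0
    for pair in pairs:
        a, b = pair[0].upper(), pair[1].upper()
        try:
            total += float(matrix[a, b])
        except (KeyError, IndexError):
            raise ValidationError(f"unknown residue in pair {pair!r}") from None
    return total / len(pairs)


@dataclass
class ExperimentReport:
    """Per-replicate records plus summary statistics for one experiment."""

    records: pd.DataFrame
    summary: dict
    seed: int
    n_requested: int

    def __post_init__(self) -> None:
        if len(self.records["replicate"].unique()) != self.n_requested:
            raise ValidationError("replicate count does not match request")

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def _conditioned_priors(priors: PriorSpec, truth: dict) -> PriorSpec:
    """Fix the drawn nuisance parameters at truth for inference."""
    return replace(
        priors,
        fixed_basis=truth["_basis"],
        fixed_shape=truth["shape"],
        fixed_clock_rate=None if priors.fixed_clock_rate is None else truth["clock_rate"],
        anchor_taxa=truth["anchor_taxa"],
    )


def _clock_estimated(priors: PriorSpec) -> bool:
    return priors.fixed_clock_rate is None


def coverage_experiment(
    n_reps: int = 20,
    n_taxa: int = 10,
    n_sites: int = 100,
    priors: PriorSpec | None = None,
    seed: int = 1,
    chain_length: int = 4000,
    thin: int = 5,
    ess_floor: float = 30.0,
) -> ExperimentReport:
    """Prior-predictive coverage (calibration) study.

    For each replicate, parameters and a tree are drawn from the prior,
    an alignment simulated, and the posterior sampled; the report records
    whether each 95% credible interval covered the truth.  Replicates
    whose chain fails the ESS floor are flagged, excluded from the
    summary, and counted.
    """
    if n_reps < 10:
        raise ValidationError("coverage studies need at least 10 replicates")
    base = priors if priors is not None else PriorSpec(fixed_clock_rate=1.0, frequency_concentration=10.0)
    params = ["te", "nu", "rootHeight", "treeLength"]
    truth_keys = {"te": "te", "nu": "nu", "rootHeight": "root_height", "treeLength": "tree_length"}
    rows = []
    for rep in range(n_reps):
        rep_seed = seed + rep
        truth, tree, aln = sample_from_prior(base, n_taxa, n_sites, rep_seed)
        pri = _conditioned_priors(base, truth)
        settings = MCMCSettings(
            chain_length=chain_length, thin=thin, seed=rep_seed,
            estimate_clock_rate=_clock_estimated(base),
        )
        trace = mcmc(aln, tree, truth["_basis"], pri, settings)
        ess = effective_sample_size(trace.parameter("rootHeight", 0.1))
        row = {"replicate": rep, "seed": rep_seed, "ess": ess, "ok": ess >= ess_floor,
               "true_Is": truth["indicator"]}
        for p in params:
            lo, hi = trace.credible_interval(p)
            tv = truth[truth_keys[p]]
            row[f"true_{p}"] = tv
            row[f"lo_{p}"], row[f"hi_{p}"] = lo, hi
            row[f"cover_{p}"] = lo <= tv <= hi
        rows.append(row)
    records = pd.DataFrame(rows)
    good = records[records["ok"]]
    summary = {"n_excluded": int((~records["ok"]).sum()), "n_used": len(good)}
    for p in params:
        cov = good[f"cover_{p}"].mean() * 100
        se = 100 * np.sqrt(0.95 * 0.05 / max(len(good), 1))
        summary[f"coverage_{p}"] = float(cov)
        summary[f"coverage_{p}_band"] = (95 - 1.96 * se, min(95 + 1.96 * se, 100.0))
    return ExperimentReport(records, summary, seed, n_reps)


def model_recovery_experiment(
    n_taxa: int = 20,
    n_sites: int = 50,
    n_reps_per_model: int = 6,
    priors: PriorSpec | None = None,
    seed: int = 1,
    chain_length: int = 4000,
    thin: int = 5,
    ess_floor: float = 10.0,
) -> ExperimentReport:
    """Simulate under null and two-alphabet truths; classify the support.

    Half the replicates are simulated with a fixed alphabet and half
    under a two-alphabet case (Is in {1,2,3} drawn uniformly); each is
    classified as "no resub" / "?" / "resub" at a Bayes factor of 10,
    dividing out the prior odds of 3:1 against the null.
    """
    base = priors if priors is not None else PriorSpec(fixed_clock_rate=1.0, frequency_concentration=10.0)
    rows = []
    rep = 0
    for truth_resub in (False, True):
        probs = (0.0, 1 / 3, 1 / 3, 1 / 3) if truth_resub else (1.0, 0.0, 0.0, 0.0)
        gen = replace(base, indicator_probs=probs)
        for k in range(n_reps_per_model):
            rep_seed = seed + 1000 * int(truth_resub) + k
            truth, tree, aln = sample_from_prior(gen, n_taxa, n_sites, rep_seed)
            pri = _conditioned_priors(base, truth)  # uniform indicator prior for inference
            settings = MCMCSettings(
                chain_length=chain_length, thin=thin, seed=rep_seed,
                estimate_clock_rate=_clock_estimated(base),
            )
            trace = mcmc(aln, tree, truth["_basis"], pri, settings)
            support = model_support(trace)
            p_resub = float(support[1:].sum())
            label = classify_support(p_resub, prior_odds=3.0)
            ess = effective_sample_size(trace.parameter("posterior", 0.1))
            rows.append({
                "replicate": rep, "seed": rep_seed, "ess": ess, "ok": ess >= ess_floor,
                "truth": "resub" if truth_resub else "no resub",
                "true_Is": truth["indicator"], "p_resub": p_resub, "call": label,
            })
            rep += 1
    records = pd.DataFrame(rows)
    good = records[records["ok"]]
    confusion = {
        (t, c): int(((good["truth"] == t) & (good["call"] == c)).sum())
        for t in ("no resub", "resub")
        for c in ("no resub", "?", "resub")
    }
    summary = {
        "confusion": confusion,
        "n_excluded": int((~records["ok"]).sum()),
        "mean_p_resub_given_resub": float(good[good["truth"] == "resub"]["p_resub"].mean()),
        "mean_p_resub_given_null": float(good[good["truth"] == "no resub"]["p_resub"].mean()),
        "false_resub_rate": confusion[("no resub", "resub")] / max(1, int((good["truth"] == "no resub").sum())),
    }
    return ExperimentReport(records, summary, seed, 2 * n_reps_per_model)


def age_bias_experiment(
    n_reps: int = 6,
    n_taxa: int = 15,
    n_sites: int = 200,
    priors: PriorSpec | None = None,
    seed: int = 1,
    chain_length: int = 5000,
    thin: int = 5,
    ess_floor: float = 10.0,
) -> ExperimentReport:
    """Root-age bias of the fixed-alphabet null on two-alphabet data.

    Data are simulated under the two-alphabet model.  A pair of internal
    clades (the children of the root's older child, where available) are
    given tight age calibrations at their true ages; the root itself is
    uncalibrated and the clock rate is estimated.  Each replicate is
    analysed twice — under the fixed-alphabet null and under the
    two-alphabet model — and the relative bias of the posterior mean
    tree height ``th`` and old-epoch duration ``th - te`` is recorded.
    """
    if n_reps < 1:
        raise ValidationError("need at least one replicate")
    base = priors if priors is not None else PriorSpec(fixed_shape=1.0, frequency_concentration=10.0)
    gen = replace(base, indicator_probs=(0.0, 1 / 3, 1 / 3, 1 / 3))
    rows = []
    for rep in range(n_reps):
        rep_seed = seed + rep
        truth, tree, aln = sample_from_prior(gen, n_taxa, n_sites, rep_seed)
        cals = _auto_calibrations(tree, max_age=0.8 * truth["anchor_height"])
        pri = replace(_conditioned_priors(base, truth), calibrations=tuple(cals))
        for condition in ("null", "resub"):
            settings = MCMCSettings(
                chain_length=chain_length, thin=thin, seed=rep_seed,
                estimate_clock_rate=_clock_estimated(base),
                estimate_indicator=(condition == "resub"),
                allowed_indicators=(0, 1, 2, 3) if condition == "resub" else (0,),
            )
            config = None
            trace = mcmc(aln, tree, truth["_basis"], pri, settings, config=config)
            th_hat = float(trace.parameter("rootHeight", 0.1).mean())
            dur_hat = float(trace.parameter("oldEpochDuration", 0.1).mean())
            th_true = truth["root_height"]
            dur_true = th_true - truth["te"]
            ess = effective_sample_size(trace.parameter("rootHeight", 0.1))
            rows.append({
                "replicate": rep, "seed": rep_seed, "condition": condition,
                "ess": ess, "ok": ess >= ess_floor,
                "true_th": th_true, "est_th": th_hat,
                "true_duration": dur_true, "est_duration": dur_hat,
                "bias_th_pct": 100 * (th_hat - th_true) / th_true,
                "bias_duration_pct": 100 * (dur_hat - dur_true) / abs(dur_true) if dur_true != 0 else np.nan,
            })
    records = pd.DataFrame(rows)
    good = records[records["ok"]]
    summary = {"n_excluded": int((~records["ok"]).sum())}
    for condition in ("null", "resub"):
        sub = good[good["condition"] == condition]
        for col in ("bias_th_pct", "bias_duration_pct"):
            vals = sub[col].dropna()
            summary[f"{condition}_{col}_mean"] = float(vals.mean())
            summary[f"{condition}_{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
    return ExperimentReport(records, summary, seed, n_reps)


def _auto_calibrations(tree, rel_sd: float = 0.02, max_age: float | None = None) -> list[Calibration]:
    """Tight LogNormal age calibrations on up to two internal non-root clades.

    With ``max_age`` set, only clades younger than it are calibrated —
    mirroring dated analyses where the young, dateable part of the tree
    carries the calibrations and everything older (the boundary and the
    root) is extrapolated.
    """
    from .mcmc import _is_descendant

    internal = [
        i for i in range(tree.n_nodes)
        if not tree.is_leaf(i) and i != tree.root
        and (max_age is None or tree.heights[i] < max_age)
    ]
    internal.sort(key=lambda i: -tree.heights[i])
    cals = []
    for node in internal[:2]:
        taxa = tuple(
            tree.labels[i] for i in tree.leaves() if _is_descendant(tree, i, node)
        )
        age = float(tree.heights[node])
        if age > 0:
            cals.append(Calibration(taxa, age, rel_sd * age))
    return cals
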