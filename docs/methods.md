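# Methods

## The two-epoch substitution model

Standard amino acid substitution models (LG, WAG, GTR-style
parameterisations) assume the 20-letter coding alphabet has been fixed
for all time. This package implements a *refinement–expansion
substitution* ("resub") model in which the alphabet itself changes at a
boundary age `te`: backwards in time, the young epoch E1 = [0, te]
carries the full m-state alphabet, and the old epoch E2 = (te, root]
carries a reduced (m−1)-state alphabet. The reduction is defined with
respect to a designated *cherry* of two states (α, β) — in the motivating
biology, the two amino acids handled by a pair of sister
aminoacyl-tRNA-synthetase families — and a model indicator `Is`:

* `Is = 0` (null): one alphabet throughout.
* `Is = 1` (refinement / subfunctionalisation): α and β were a single
  merged low-specificity state in E2. The merged state takes frequency
  `π_α + π_β` and frequency-weighted exchangeabilities, reflecting the
  assumption that the merged state sits at equilibrium between its
  sub-states.
* `Is = 2, 3` (expansion / neofunctionalisation): one cherry state was
  absent from E2; the remaining frequencies renormalise.

Within each epoch the process is a reversible CTMC: `Q = r·diag(π)` with
zero row sums, normalised so the expected rate at equilibrium is one
substitution per site per unit time, and `P(τ) = expm(q(Q)·τ)`. At the
boundary an (m−1)×m row-stochastic *saltation matrix* Ξ applies one
instantaneous, tree-wide jump: the retained cherry state transfers to
the newly coded state with probability ν, and every other state leaks
into the new state(s) in proportion to the modern equilibrium
frequencies. A branch spanning the boundary with old-epoch distance τ₂
and young-epoch distance τ₁ has transition probabilities
`P′(τ₂) · Ξ · P(τ₁)`, a rectangular matrix with rows on the old
(reduced) alphabet and columns on the young (full) one.

Epochs are half-open: E2 = (te, root], so a node exactly at the boundary
belongs to the young epoch. When `te` is at or above the root (or
origin), the old epoch is empty and the model degenerates to the null
case; this is legal, merely made rare by the boundary prior.

## Likelihood

`tree_log_likelihood` runs Felsenstein pruning with epoch-aware state
spaces: partial-likelihood vectors above the boundary live in the
reduced alphabet, boundary-crossing branches apply the rectangular
composite matrix, and the root (or origin, when a stem branch is
present) vector is dotted with the stationary frequencies of the oldest
epoch present. Site-rate heterogeneity uses the discrete-gamma
construction with four equal-probability categories (mean-of-interval
rates, rescaled to average one exactly); categories are averaged with
equal weights in log space. Gap and ambiguity codes (`-`, `X`, `?`
fully ambiguous; `B`, `Z`, `J` two-state sets) are marginalised through
all-ones / set-indicator leaf partials. Per-node rescaling with
accumulated log scalers keeps deep alignments finite. Site patterns are
compressed with counts before any computation.

Numerical route: the user-facing `transition_matrix` uses the dense Padé
matrix exponential; the likelihood engine and simulator use the
symmetric spectral decomposition of `diag(√π)·q(Q)·diag(1/√π)` (exact
for reversible processes, and batched over all branch × category
distances in one call). Both routes satisfy Chapman–Kolmogorov to 1e-9
in the test suite, and the pruning engine matches an independent
exhaustive-enumeration oracle to 1e-10 on small trees.

A dated leaf older than the boundary is observed in the full alphabet
but evolves in the reduced space; its observation is projected into the
reduced space with the merged state weighting its sub-states by their
modern equilibrium ratio (the simulator emits sub-states at the same
ratio, so simulation and likelihood agree in distribution).

## Tree prior and simulator

Trees follow a birth–death(-sampling) process with birth rate λ,
reproduction number R0 = λ/μ and sampling fraction ρ, conditioned on the
number of sampled extant taxa with a uniform prior on the (marginalised)
time of origin. Writing r = λ−μ and
`η(t) = λρ(1−e^{−rt}) / (λρ + (λ(1−ρ)−μ)e^{−rt})`, the origin age has
CDF `η(t)^n`, and given the origin the n−1 speciation ages are i.i.d.
with CDF `η(s)/η(t_or)`; ranked topologies are uniform and independent
of the ages. The simulator draws trees constructively from this point
process, and the MCMC sampler uses the matching fixed-topology density
`∝ Π_i λ·p1(h_i) · (1 − η(h_root))` obtained by marginalising the
origin (`p1 = η′/λ` is the one-sampled-descendant probability). Because
sampler and density derive from the same process, prior-only MCMC
reproduces the direct simulator's root-age distribution — a test the
suite runs. Supercritical processes only (R0 > 1); subcritical
conditioning is not supported. A forward-time mode (dendropy, GSA
conditioning) retains dated extinct tips for serially sampled designs.

The sequence simulator evolves each site independently down the tree:
category draw, stationary root state, per-branch CTMC transitions, and
one categorical draw from the saltation row at the instant a lineage
crosses the boundary. Leaves always emit full-alphabet characters.

## Priors and MCMC

The posterior combines the pruning likelihood, the birth–death tree
density, and:

* `te − t_anchor ~ Laplace(0, δ)`, where `t_anchor` is the age of the
  anchor (cherry) clade — a node of the tree, so the prior follows that
  node's age during sampling. Default δ = 0.05 in the tree's time
  units; te is constrained non-negative.
* `Is ~ Categorical(uniform over {0,1,2,3})`; Bayes factors divide out
  the prior odds so the strong-support threshold of 10 is independent of
  this split.
* `ν ~ Uniform(0,1)`; π flat Dirichlet; exchangeabilities i.i.d.
  Exponential(1); gamma shape and clock rate LogNormal, parameterised by
  real-space mean and standard deviation (shape: mean 1, sd 0.5; clock:
  mean 1, sd 0.3).
* Optional clade-age calibrations: LogNormal(M, S in real space) on
  named MRCA ages. The dated-analysis defaults (units Ga) are Root
  (4.49, 0.00375), LUCA (4.25, 0.0094), LACA (3.35, 0.0114), LBCA
  (3.25, 0.0142), LMCA (1.43, 0.0589), LECA (1.32, 0.0443).
* Cross-bracing for co-dated tree pairs: Exponential(mean 0.01 Ga)
  densities on the absolute root-age difference and on the mean absolute
  difference across braced node pairs.

Sampling is Metropolis–Hastings with: random-walk moves on te (and a
reflected walk on ν); a uniform resample of `Is` plus an independence
jump that redraws (Is, te, ν) from their priors (its Hastings ratio
cancels the prior terms, so the likelihood ratio decides — this is what
makes trans-model mixing fast); uniform node-height slides, a root
scale, and a whole-tree scale that carries te along; a joint
anchor-age + te translation (the tightly coupled pair moves together); a
scaled-Dirichlet simplex move for π; per-element log-walks on r; log
walks on shape and clock rate; and an optional symmetric narrow
(uncle–nephew) exchange when topology is sampled. `ν` and `te` remain
in the state under `Is = 0`, where the likelihood ignores them — a
pseudo-prior construction that avoids reversible-jump bookkeeping and
changes no marginal of interest. Operator step sizes self-tune towards
~30% acceptance with diminishing adaptation (step ∝ 1/√k), which
preserves ergodicity. Convergence is assessed with the
initial-monotone-sequence (Geyer) effective sample size, summed across
independent chains; the convention of two chains with combined ESS > 200
applies to full analyses.

## Simulation studies (and their scales)

Three harnesses validate the implementation end to end. All follow the
simulate-from-the-prior → infer → compare protocol and run, by default,
at deliberately reduced sizes chosen so a complete study finishes in
minutes on one CPU; keyword arguments scale them up.

In every harness the exchangeability matrix, frequencies, gamma shape
(and, where noted, clock rate) are drawn from their priors per replicate
and then **conditioned on** — held at their true values during
inference. The estimated quantities are the epoch parameters (Is, te,
ν) and the time-tree. This conditioning is exact (the same values enter
simulation and inference), so calibration statements remain valid for
the estimated parameters; it does not exercise the π/r samplers, which
are validated separately in unit tests and available through the CLI.

* **Coverage** (default 20 reps; the acceptance suite runs 50 at N=10,
  L=100, m=20): 95% credible intervals for te, ν, root height and tree
  length should cover truth for ~95% of replicates, within the binomial
  band. Replicates failing an ESS floor are flagged, excluded and
  counted.
* **Model recovery** (N=20, L=50 and 200): data simulated 50/50 under
  the null and under the two-alphabet model, classified at Bayes factor
  10 (prior odds 3:1 divided out). Expected behaviour: the correct call
  is modal, confidently wrong calls are rare, and confidence grows with
  L. At L=50 a fraction of replicates are honestly ambiguous ("?").
* **Age bias** (default 5–6 reps at N=12–15, L=200): data simulated
  under the two-alphabet model; up to two internal clades *younger than
  the epoch boundary* (ages below 0.8× the anchor age) receive tight
  LogNormal calibrations at their true ages, the root is left
  uncalibrated, and the clock rate is estimated. This mirrors dated
  analyses in which the young, dateable part of the tree carries the
  calibrations while the boundary and root are extrapolated — the
  pre-boundary region must be free for the bias to be measurable.
  Re-estimating under the fixed-alphabet null overestimates the
  old-epoch duration (th − te) and the tree height th; the
  two-alphabet model recovers both with small bias.

The boundary anchor in simulated studies defaults to the internal node
whose age is nearest 55% of the root age: the boundary is meant to sit
near an ancient functional bifurcation — old, but with tree above it.
Anchoring immediately below the root would make the true old-epoch
duration nearly zero and relative biases meaningless.

Two distributions govern the frequency vector π. The *estimation*
prior (used whenever π is sampled by MCMC) is the flat Dirichlet. The
*study generator* draws π from Dirichlet(10) by default
(`PriorSpec.frequency_concentration`), giving protein-like frequencies
of roughly 2–9% per residue. Flat-Dirichlet draws on 20 states
routinely leave the cherry amino acids at negligible frequency, so
simulated alignments would contain almost no cherry residues and the
epoch machinery would be untestable. Because π and r are conditioned
on in every harness, this generating choice does not affect coverage
calibration of the estimated parameters.

What the synthetic data do not emulate: real alignments have
site-correlated indels (gaps here are missing-at-random), alignment
error, model misspecification in r (drawn from the prior rather than
LG-like), lineage-specific rate shifts beyond a lognormal relaxed
clock, and more than one alphabet transition. Passing these studies
therefore demonstrates internal correctness and calibration of the
machinery, not that empirical aaRS datasets will show any particular
support pattern.

## Numerical choices and edge cases

* Transition probabilities are clipped at 0 and row-renormalised after
  exponentiation (round-off is ~1e-16).
* `normalize_rate_matrix` rejects an all-zero generator
  (non-positive normaliser).
* Equal node heights are rejected (`parent > child` strictly); the
  boundary exactly at a node height assigns the node to the young epoch.
* The Laplace boundary prior is sampled by rejection below zero but its
  density is left untruncated; with anchors at sensible ages the
  truncated mass is ~e^{−20}.
* Pattern-likelihood zeros (impossible patterns under expansion above
  the boundary) propagate as −inf log likelihoods, never NaNs.
* Mean-of-interval discrete-gamma rates have spread ≈ 1.27/√shape, so
  the vanishing-variance regime is only reached for very large shapes.

## Known limitations

* One cherry and two epochs per analysis; multi-epoch alphabets are out
  of scope.
* Topology sampling is limited to narrow exchanges and is not intended
  for serious tree search; analyses here fix the topology and sample
  node times.
* The birth–death density used with serially sampled (extinct) tips
  treats tip dates as fixed data and applies the extant-conditioned
  density to internal nodes — a pragmatic prior, not the full
  birth–death-sampling-through-time density.
* No marginal-likelihood estimators (path sampling); model comparison
  is by indicator-variable model averaging only.
* Stochastic variable selection on exchangeabilities is not
  implemented.
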