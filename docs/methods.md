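# Methods

## The estimation problem

A biomolecular pathway is modeled as a causal latent-variable model (LVM): a
DAG over observed variables **V** (measured transcripts, proteins, activity
read-outs) and latent variables **U** (unmeasured regulators, hidden
confounders), with the joint density factorizing as
`P(U, V) = prod_j P(V_j | Pa(V_j)) * prod_l P(U_l | Pa(U_l))`.
The quantity of interest is an interventional query `P(Y | do(X = x'))` or its
expectation: what happens to outcome Y when targets X are clamped to x' —
a knockout, an over-expression, a drug dose — while only *observational* data
are available for training.

Estimation follows the identify–mutilate–sample recipe:

1. **Identify.** Project the explicit-latent DAG onto an acyclic directed
   mixed graph (ADMG) over observed nodes, and decide with do-calculus
   whether the query is identifiable, i.e. expressible as a do-free functional
   of the observational distribution. Non-identifiable queries are *refused*
   (exit code 2 from the CLI) — any number the sampler would produce depends
   on arbitrary non-identified parameters.
2. **Train.** Fit the LVM to observational data with Hamiltonian Monte Carlo,
   obtaining posterior draws of every parameter (and of the per-replicate
   latent values).
3. **Mutilate and sample.** Sever the edges into the intervention targets,
   clamp them at x', and for each of S posterior parameter draws ancestrally
   sample all of U ∪ V in topological order L times, pooling the outcome
   values. The pooled sample is the posterior-predictive interventional
   distribution; its mean estimates `E[Y | do(x')]`.

The point of the surrounding theory is that step 3 is trustworthy *exactly
when* step 1 succeeds, even though individual parameters (confounder weights,
latent scales) are not identified and their posteriors never concentrate, and
even when the assumed number of latent variables is wrong, provided the wrong
model projects onto the same ADMG. The test-suite experiments reproduce both
phenomena.

## Identification

Three routes are tried in order, and the successful one is reported, because
pathway analyses conventionally state *which* criterion applied:

- **Back-door** (single cause/outcome): search for an observed adjustment set
  Z with no member a descendant of X, no bidirected-only path X–Y, and all
  arrow-into-X paths blocked; estimand `sum_z P(Y|x',z) P(z)`. The search is
  exhaustive over subsets of eligible nodes, smallest first (graphs here have
  at most ~13 observed nodes; the subset scan is capped at 4096 candidates).
- **Front-door** (possibly multi-cause): search for a mediator set Z
  intercepting every directed X→Y path, with no back-door from X to Z open
  given ∅ (tested in the graph with X's outgoing edges removed, which is what
  makes the multi-cause generalization correct), and Z→Y back-doors blocked
  by X; estimand `sum_z P(z|x') sum_x P(Y|x,z) P(x)`.
- **Complete identification**: the district (c-component) based recursive
  algorithm over the ADMG. It either returns an estimand built from sums,
  products, fractions and observational conditionals, or exhibits a hedge —
  a single confounded component spanning the intervention set — which proves
  non-identifiability (the do-calculus is complete for this query class).

Estimands are expression trees; they render to plain text and JSON and can be
evaluated numerically against any discrete joint table. Two conventions
matter for evaluation: conditionals on zero-mass events contribute zero (the
front-door precondition `P(x, z) > 0` is the user's responsibility and is
surfaced in plug-in error messages), and ratio-form estimands (napkin-type)
may retain free *context* variables whose value is provably irrelevant under
the model — positive-mass context slices are averaged with observational
weights rather than evaluated at an arbitrary point.

Estimand equality is never tested syntactically: when two routes identify the
same query their estimands are compared by evaluation on random discrete
parameterizations, which avoids false mismatches from algebraic
rearrangement.

## Distribution families

Every node follows a family whose location is a linear predictor
`eta = intercept + sum_p w_p * parent_p`:

| family | law | used for |
|---|---|---|
| `gaussian_linear` | `eta + N(0, sigma)` | relative expression (RT-PCR-like), latent regulators |
| `bernoulli_logit` | `Bern(logistic(eta))` | binarized regulatory states |
| `gamma` | `Gamma(mean = exp(eta), shape)` | fluorescent-reporter intensities (log link keeps the mean positive) |
| `hill_sigmoid` | `N(cap * logistic(eta), sigma)` | saturating protein responses, `cap = 100` molecules |
| `point` | degenerate at a value | intervened nodes after mutilation |

The Hill-sigmoid sign convention is `cap / (1 + exp(-eta))`: a
positive weight *increases* the mean, so the constraint "positive for
*increase* edges, negative for *decrease* edges" reads the way a biologist
expects. (With the opposite sign convention, `cap / (1 + exp(+eta))`, the
stated constraint semantics would be inverted; the two are equivalent up to
negating every weight, and this package fixes the intuitive one.)

Intercept-with-noise is used for the structural equations: a structural term
"θ_X ~ N(mu_X, sigma_X)" is implemented as `intercept mu_X` plus
`N(0, sigma_X)` noise, which is the same Gaussian by closure.

## Inference

The posterior is sampled with a No-U-Turn sampler written against analytic
per-family gradients:

- **Per-replicate latents.** Latent node values enter as local parameters,
  one per data row. This keeps the scheme family-generic (latents feeding
  Bernoulli, gamma or Hill nodes need no special casing). Both the
  *non-centered* form `u_i = eta_i + sigma * eps_i`, `eps_i ~ N(0,1)` (the
  default) and the *centered* form (u sampled directly under its
  `N(eta_i, sigma)` prior) are implemented and gradient-checked
  (`latent_param=`). Hidden pathway regulators are typically only weakly
  informed by each replicate, which is the regime where non-centered
  geometry is benign; the centered form is prone to collapsing into the
  small-`sigma` funnel neck there (observed as a tightly reproducible but
  biased latent-scale posterior) and should be reserved for latents with
  many informative children. Adaptation budget matters more than the
  parameterization at large n: the napkin-motif fits, for example, need
  ~400 warmup iterations and tree depth 6 before the latent channel is
  explored well enough for interventional estimates to settle.
- **Collapsed all-Gaussian likelihood.** When every node is Gaussian the
  per-row latents are marginalized exactly: the observed vector is
  multivariate normal with mean `(A b)_O` and covariance `(A D A^T)_OO`,
  `A = (I - B)^{-1}` for the weight matrix B. The likelihood then depends on
  the data only through its first two moments, so the gradient cost is
  independent of n. Selected automatically (`method="auto"`).
- **Constraints.** Positive parameters (noise scales, gamma shapes,
  increase-edge weights) are sampled as `exp(z)`, negative ones as `-exp(z)`,
  with the log-Jacobian added; priors are the declared (possibly truncated)
  normals.
- **Adaptation.** Dual-averaging step size toward a target acceptance of
  0.85, with a diagonal mass matrix re-estimated on expanding warmup windows
  (15% fast start, doubling slow windows, 10% fast tail).
- **Defaults.** 2 chains, 500 warmup, 500 kept draws, maximum tree depth 8.
  The repeat-heavy experiments use 250/200 with depth 5: the slow directions
  of these posteriors are precisely the non-identified parameter ridges, and
  the query estimate — a posterior-predictive functional — equilibrates much
  faster than those ridges, so short trajectories trade parameter-level
  mixing (which provably cannot converge anyway) for wall-clock time without
  moving the query estimates beyond their Monte-Carlo noise.
- **Diagnostics.** Split-R-hat and bulk ESS per parameter (arviz), divergence
  counts, and a report that deliberately separates parameter-level flags from
  data-level adequacy: in non-identified models low per-parameter ESS
  coexists with a perfectly calibrated posterior predictive, and collapsing
  the two into one verdict would mislead.

Initialization is data-informed and jittered: noise scales start at column
standard deviations, informative-prior parameters at their prior centers,
and intercepts at the value that matches the observed node mean under the
family's link. Sign-constrained weights start at a scale inverse to their
parent's spread (±0.25 / sd(parent)). The last two choices are load-bearing
for saturating families: a Hill-sigmoid node initialized with a unit weight
on a ~100-molecule parent sits at its cap, where the weight gradient
vanishes and no sampler escapes — the chain then converges to a degenerate
"saturated mean + inflated noise" mode that badly biases interventional
estimates. Starting inside the responsive region avoids that trap.

## Synthetic study conditions

The benchmark systems (two motivating examples and six case studies) fix
their true parameters by drawing once, at a recorded seed, from moderate
generating laws: weights near ±0.8 (±0.04 on the 0–100 molecule scale of
Hill nodes, ±0.3 on the log scale of the gamma reporter), unit-scale
intercepts and noise, gamma shape ≈ 4. These are deliberately narrower than
the non-informative N(0, 10) *inference* priors: parameters drawn from the
wide prior routinely saturate logits and sigmoids, producing degenerate
(constant) nodes that make interventional queries trivial. The generating
laws are part of the study conditions, fixed in the builders, and not tuned
per experiment.

The signaling case study draws its data from a Gillespie stochastic
simulation of the mass-action network (catalytic production `A -> A + B` for
activation, catalytic degradation for inhibition, first-order decay, all
species initialized at 100 molecules, growth-factor inputs randomized per
replicate on 40–160). The published system is characterized only up to its
stochastic dynamics; the rate constants here (production 0.5, decay 0.5,
inhibition 0.002) are chosen to hold species near the 100-molecule scale and
are configurable. The fitted Hill-sigmoid LVM only *approximates* this jump
process — that mismatch is the point of the exercise, not a nuisance.

What the synthetic generators do **not** emulate: dynamic-range compression
and heteroscedastic measurement error of real RNA-seq compendia, dependence
between experimental conditions, batch structure, and feedback regulation
(the models are acyclic by construction). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated families, not
robustness to every artifact of experimental data. The expression-compendium
case studies run on synthetic stand-ins drawn from their stated Gaussian
models; a loader for a user-supplied expression CSV in the same shape is the
intended path for real data.

## Problem sizes in the shipped experiments

The published protocol uses 20 data regenerations per training-set size and
HMC runs of minutes to hours per fit. The shipped test suite runs the same
experiment designs at desk scale, as a deliberate package choice:

- mediated-pair consistency: n ∈ {50, 300, 10 000}, 6 repeats (the collapsed
  all-Gaussian likelihood makes fit cost independent of n, so the largest
  design point costs no more than the smallest);
- multi-cause feed-forward consistency: n ∈ {50, 300, 1200}, 3 repeats;
- napkin consistency/robustness: correct variant over {50, 400, 5000} and
  the misspecified variant at the endpoints, 3–4 repeats, with the largest-n
  fits given the longer adaptation budget noted above;
- 2 chains × (250 warmup + 200 kept) draws with tree depth 5 for all other
  repeat-heavy fits; simulation truths from 10 000 interventional samples
  (1000–2000 for the jump-process system, whose sampling is the costly path).

Design points are spaced so adjacent RMSE levels differ by ~3x, which keeps
the monotonicity checks stable at these repeat counts. All tolerances are
expressed in Monte-Carlo standard errors computed from the actual repeats,
so the scaled-down designs are exactly as demanding per draw as the
full-size ones.

## Numerical choices and edge cases

- Linear predictors are clipped to ±30 before `exp`/`logistic`; non-finite
  log-posterior evaluations return −∞ and are rejected as divergences.
- Topological order breaks ties lexicographically, so seeded runs are
  bit-reproducible across platforms.
- All randomness descends from one user seed through labeled
  `SeedSequence` derivations (chain seeds, per-repeat data seeds, quadrature
  of plug-ins); no global generator state is used anywhere.
- Mutilation removes bidirected edges incident to targets: an intervention
  cuts *all* incoming influence, latent confounding included.
- Interventions on latent nodes are rejected. The underlying theory would
  permit them, but a latent intervention is experimentally meaningless
  (there is nothing to clamp), and allowing it would silently change the
  latent projection.
- `validate_model` is report-based (a list of violations) rather than
  exception-based so model builders can collect all problems at once; the
  `CausalLVM` constructor enforces validity by raising on a non-empty report.

## Known limitations

- Plain HMC mixes slowly along non-identified ridges; parameter-level R-hat
  on confounder weights is expected to be poor in exactly the cases the
  theory says those parameters cannot be learned. Judge fits by the
  diagnostics report's separation of parameter-level and data-level checks.
- The collapsed likelihood exists only for all-Gaussian models; mixed-family
  models at large n pay the per-row-latent cost.
- Identification handles unconditional interventional queries
  `P(Y | do(x'))`; conditional effects `P(Y | do(x'), w)` and counterfactual
  (layer-3) queries are out of scope, as are cyclic models, selection bias
  and time-series structure.
- The front-door/back-door witness search is exhaustive over subsets and
  intended for pathway-scale graphs (tens of nodes), not genome-scale ones;
  the complete ID algorithm itself is polynomial and is always available as
  the fallback.
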