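# Methods

## The modeled quantity: log response times

All diffusion quantities live on the natural-log scale of response times in
milliseconds. The published group estimates this package uses as simulator
defaults (non-decision time ≈ 7.5, boundary separation ≈ 2.5) are only
dimensionally consistent with ln(RT in ms): exp(7.5) ≈ 1800 ms is a
plausible non-decision floor, whereas 7.5 s or 7.5 on a seconds-log scale
is not. The package therefore models ln(RT_ms) throughout: the Wiener
process's "decision time" is ln(RT_ms) − t0, and simulated RTs are
exp(t0 + decision time). A consequence worth knowing is that the implied
RT distribution is heavy-tailed on the millisecond scale (simulated trials
occasionally run to tens of seconds); that is a property of the log-scale
diffusion itself, not of this implementation. The diffusion coefficient is
fixed at σ = 1; parameter values are only meaningful relative to that
convention.

## Wiener first-passage numerics

The defective first-passage density uses the classic pair of series
representations (small-time expansion in images of the start point,
large-time expansion in sine modes), choosing per evaluation whichever
needs fewer terms at truncation tolerance 1e-7. Accuracy is verified by
quadrature (joint normalization to 1 ± 1e-4 across a parameter grid),
against the closed-form absorption probability
P(upper) = (1 − e^{−2vaz}) / (1 − e^{−2va}), and by exact reflection
symmetry (z → 1−z, v → −v swaps the boundaries).

Across-trial starting-point variability sz (uniform on z ± sz/2) enters the
likelihood by 11-node Gauss–Legendre quadrature over the range — the
integrand is smooth, so a fixed-node rule is cheap and deterministic; a
Monte-Carlo average over 10⁴ uniform starts agrees to 1e-3.

The brute-force oracle (and the data generator) is an Euler–Maruyama path
simulator with Brownian-bridge crossing correction: at each step the
probability of an unobserved within-step boundary crossing,
exp(−2(a−x)(a−x′)/dt) for the upper and exp(−2xx′/dt) for the lower
boundary, is sampled. This removes the O(√dt) absorption bias of naive
Euler schemes, which at dt = 1e-4 would otherwise exceed the Monte-Carlo
error of 10⁶-path comparisons. Default step dt = 1e-4 (log-RT units).

## Boundary and sign conventions

The upper boundary always encodes the desirable-state judgment, so a
starting point above 0.5 and a positive drift bias both mean "toward
desirable conclusions", matching the sign language used when the group
estimates were reported. The drift regression v = β₀ + β₁·desirability
(desirability 1 on desirable-state trials, 0 otherwise) sets the drift
*magnitude toward the correct boundary*; the signed drift toward the upper
boundary is +(β₀+β₁) on desirable trials and −β₀ on undesirable trials.
The valence-independent models are the exact β₁ = 0 special case, which
makes the family nested and the likelihood equivalence testable.

## Hierarchical model and priors

Subject-level parameters are drawn from group-level normals on transformed
scales — log a, log t0, logit z, identity for β₀ and β₁ — which is standard
hierarchical practice for bounded parameters. Group means carry flat
priors within generous physical bounds (a ∈ (0.3, 6), t0 ∈ (0.01, 10),
z ∈ (0.05, 0.95), drift terms ∈ (−5, 5)), implementing "equal probability
over all possible values" while keeping the sampler on physically sensible
ground. Group spreads are half-normal (scales 0.5, 0.5, 1.0, 0.5, 0.5 on
the sampling scales — weakly informative relative to the spreads actually
observed). sz is a single group-level scalar with a flat prior on
[0, 0.6), mirroring common practice for inter-trial parameters, and is
included in all four specifications.

## Sampler

No probabilistic-programming backend is used; the sampler is an adaptive
Metropolis-within-Gibbs scheme written for this likelihood:

* subject-level parameters: coordinate-wise Gaussian random-walk
  Metropolis against the subject's trial likelihood plus its group prior;
* group means: conjugate normal draws given the subject values and group
  spread (flat prior; draws outside the bounds are rejected and redrawn);
* group spreads: random-walk on log σ with the half-normal prior and
  Jacobian;
* sz: random-walk against the full-group likelihood.

Proposal scales adapt toward ~0.44 acceptance every 25 iterations *during
burn-in only* and are frozen afterwards, so retained draws come from a
valid time-homogeneous chain. Chains are seeded via `SeedSequence(seed,
chain_index)`; identical seed and data give bit-identical chains.
Initialization is data-informed (t0 just below each subject's minimum
log-RT, neutral values elsewhere, seed-jittered) with bounded retries on
non-finite starts. `n_samples` counts total iterations per chain,
`n_burn` of which are discarded (the study's convention: e.g. "2,000
samples, 500 burn-in" means 1,500 retained).

Convergence is assessed with the classic Gelman–Rubin statistic (between-
vs within-chain variance; R̂ < 1.1), computed on the sampling scale; the
hand-written implementation is cross-checked against arviz in the tests.

## DIC

DIC = D(θ̄) + 2pD with pD = mean(D) − D(θ̄), deviance D = −2 log p(data |
subject parameters, sz). The deviance at the mean evaluates the posterior
mean of each parameter *on its sampling scale*; DIC is not invariant to
that choice, so it is fixed and documented here. Lower is better.

## The generator's study conditions

The simulator's defaults are the task's stated conditions: 80 trials per
subject, equal prior over the two states, item–state match probability
0.6, ~521 ms mean stimulus presentation with a 150 ms lag. Presentation
time is uniformly jittered (±150 ms half-width) — the simplest
distribution consistent with the reported means; the real jitter
distribution differed between testing sites and is not fully reported, so
the half-width is configurable.

Group-level generating parameters default to the published control
(α 2.67, t0 7.55, z 0.48, sz 0.18, β₀ 0.46, β₁ 0.17) and threat
(2.47, 7.49, 0.51, 0.19, 0.63, −0.08) estimates. Between-subject spreads
are not reported; the defaults (sd 0.08 on log a, 0.013 on log t0, 0.15 on
logit z, 0.15 on β₀, 0.12 on β₁) were chosen once to match the visible
between-subject scatter of reported subject-level drift-bias estimates
(roughly ±0.25 around the group mean) and modest individual differences in
speed and caution; they are parameters of `GroupParams` and can be set
freely.

Because the fitted DDM ignores the discrete stimulus structure, DDM
datasets sample (choice, log-RT) directly from the diffusion and attach a
stream whose length is the number of items presentable within the realized
RT; psychometric datasets instead generate the stream first, truncate it
at a sampled stopping count (default 2 + Poisson(4) items — the real
stopping distribution is unreported, so the rule is a configurable
callable), and draw the choice from the logistic. Each downstream analysis
is thereby tested against exactly the generative model it assumes. Win/loss
point magnitudes never affect judgments and are not simulated.

What passing tests on these data do *not* show: robustness to the ways
real data violate the model — non-log-normal RT contaminants, attention
lapses, sequential dependencies between trials, site differences in
stimulus timing, or subjects whose stopping behavior depends on the
evidence itself (the psychometric generator's stopping rule is independent
of the stream).

## Psychometric function

P(TV) = 1 / (1 + e^−(β₁X − β₀)) is implemented verbatim, with X the
centered observed TV proportion and indifference point β₀/β₁. Note a sign
wrinkle: under this formula a *larger* β₀ moves the curve right (more TV
evidence required), while verbal descriptions accompanying the published
estimates describe the direction the other way; the package follows the
formula and makes no silent sign flip, so cross-report comparisons should
use the indifference point. The primary estimator is pooled per-condition
maximum likelihood (statsmodels Logit) with subject-resampling bootstrap
confidence intervals — at the simulator's scale this targets the same
fixed effects as the original mixed-effects fit while remaining simple and
fully testable. Complete separation triggers a small ridge penalty
(1e-3 β₁² + 1e-4 β₀²) with a warning.

## Exclusion rules

Fixed order (the rules are published, their order is not): (1) flag trials
answered before the second item; (2) drop subjects flagged on *more than
half* their trials (exactly half is retained); (3) drop remaining flagged
trials; (4) drop subjects with accuracy *strictly below* 0.5 on the
retained trials. The cascade is deterministic and idempotent. The
mixed-effects F-tests on proportion correct are replaced by a seeded
subject-level permutation test of the group × valence interaction, which
is self-contained and assertable on synthetic data.

## Problem sizes

Recovery experiments in the test suite run at
the study's own 43/40-subject scale with 3 chains of 2,500 iterations
(500 burn-in); the acceptance script uses 3 chains of 4,000 iterations
(1,000 burn-in) at the same scale for extra convergence headroom. The ten-replicate
sign-pattern check runs at 10 subjects × 80 trials, single chain. The
four-model DIC comparison uses 16 subjects × 80 trials generated from a
configuration in which both valence-dependent mechanisms are clearly
present (z = 0.58, β₁ = 0.17): with starting points as close to 0.5 as the
published group means (0.48–0.51), small simulated samples cannot reliably
separate the starting-point models from their fixed-z counterparts, so the
model-selection property is exercised where the generating model is
actually identifiable at desk scale.

## Known limitations

* No across-trial drift variability (sv) or non-decision-time variability
  (st): the model family under study includes neither.
* sz is weakly identified at desk scale; its posterior is broad and its
  chains mix the slowest (R̂ typically ~1.04 where other parameters sit at
  1.00–1.03).
* DIC values depend on the deviance-at-mean convention above and on
  hierarchical focus; only differences between models fitted identically
  are meaningful.
* The path simulator's time discretization (dt = 1e-4) leaves an O(dt)
  bias in decision times after bridge correction — negligible against
  Monte-Carlo error at the scales tested, but not exactly zero.
* The mixed-effects (random-slope) psychometric variant is not
  implemented; pooled-with-cluster-bootstrap is the supported estimator.
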