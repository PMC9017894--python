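# Methods

## The behavioural model

`oddlearn` models trial-by-trial learning in a two-alternative texture
oddball-detection task. On each trial an observer reports whether a briefly
presented grid of oriented lines contains a single offset element; the
stimulus onset asynchrony (SOA, the time between stimulus and mask) controls
difficulty and takes one of seven values between 15 and 500 ms. Correctness
on trial *t* of participant *p* is Bernoulli with probability given by a
chance-floored Quick (base-2 Weibull) psychometric function,

    P(correct) = γ + (1 − γ − ε) · (1 − 2^(−(x/θ_p(t))^β_p)),

with guessing floor γ = 0.5 (two alternatives), lapse rate ε, shape β_p, and
a threshold θ_p(t) that improves exponentially with practice on the log
scale:

    log θ_p(t) = A_p + (S_p − A_p) · 2^(−(t − 1)/10^{R_p}).

At x = θ with ε = 0 the function passes through 0.75, so θ is the
75%-correct threshold. `S_p` is the log starting threshold (trial 1 exactly),
`A_p` the log asymptotic threshold, and `10^{R_p}` the number of trials after
which half of the log-threshold change has occurred (a base-2 decay kernel;
an e-folding kernel would be an equally defensible convention — this one is
chosen so that `R` reads directly as "log₁₀ trials to half-change").

Each component (A, S, R, and log β) decomposes into group fixed effects and
a by-participant Gaussian random effect. Conditions are coded as in the
study design the package targets: age −0.5 (child) / +0.5 (adult); arousal
−0.5 (control) / +0.5 (positive or stress); valence as a *monotonic* ordinal
effect (stress < control < positive). The monotonic effect is parameterised
as a total coefficient times cumulative simplex weights, `b_v · Σ_{i≤x} ζ_i`
with ζ ~ Dirichlet(1, 1), which enforces order-preservation without
linearity. One simplex is shared across the three components (and scaled by
the age interaction where present); per-component simplexes would be the
other defensible choice, at the cost of two extra weakly-identified
parameters. In the per-age valence models the predictor collapses to a
binary ±0.5 contrast between stress and positive, and only those two
conditions' data enter the model — including its null partner, so that
Bayes factors compare models of the same data.

Shape is per-participant but constant over trials. The lapse rate is fixed
at ε = 0.01 by default; an `estimated` mode places a Beta(2, 60) prior on
ε/0.5. With a fixed small lapse the likelihood never becomes degenerate for
saturated trials.

### Priors

All priors are proper (a requirement for marginal likelihoods) and weakly
informative on the link scales, chosen for a task with SOAs of 15–500 ms and
a couple of hundred trials:

| parameter | prior | rationale |
|---|---|---|
| A intercept | Normal(−2.5, 1) log-s | thresholds of order 100 ms |
| S intercept | Normal(0, 1.5) log-s | start thresholds up to a few s |
| R intercept | Normal(log₁₀ 50, 0.7) | half-change of tens of trials; soft-bounds 10^R to ≈ [1, 5·n_trials], preventing S/A aliasing when no learning occurs |
| condition/age coefficients | Normal(0, 1) | one log-unit effects are large |
| random-effect SDs | half-Normal(0, 1) | |
| log shape | Normal(log 3, 0.5) | typical psychometric slopes |
| ζ | Dirichlet(1, 1) | uniform over monotone profiles |

The full unnormalised posterior includes every prior's normalising constant
and all transform Jacobians, so that bridge sampling integrates it to the
marginal likelihood.

## Screening and analysis window

Participants unable to do the task respond at the 50% floor. They are
removed by an exact one-tailed binomial test of overall accuracy against
0.5 (upper tail, over **all** trials, no normal approximation), excluding
participants with p ≥ .05 (strict inequality). Screening always precedes
truncation; the learning models are then fitted to only the first 200
trials (`max_trial=None` keeps all trials for sensitivity analysis).

## Posterior computation

No probabilistic-programming framework is used; the sampler is part of the
package:

* **NUTS** (multinomial state selection, biased progressive sampling,
  energy-error divergence threshold 1000, max tree depth 8) on the
  unconstrained parameter vector, with analytic gradients; the per-trial
  likelihood/gradient kernel is numba-compiled and verified against finite
  differences in the test suite.
* **Warmup**: Stan-style three-phase schedule (15% initial step-size phase,
  doubling variance-estimation windows, 10% terminal phase) adapting a
  diagonal metric and a dual-averaged step size.
* **Initialisation**: chains start near an L-BFGS approximation of the
  posterior mode (per-chain Gaussian jitter 0.05), and the diagonal metric
  is seeded from the inverse Hessian diagonal at that mode (central finite
  differences of the analytic gradient). Both shorten warmup considerably.
  `init="random"` falls back to jittered prior locations.
* **Random effects** are non-centred by default (`u = σ·z`), which mixes
  better when some participants' components are weakly identified (e.g.
  rate for near-asymptotic learners); a centred parameterisation is
  available and the test suite verifies that both describe the same
  posterior density up to the transform Jacobian.
* **Self-healing**: when adaptation visibly failed (split R̂ > 1.3, more
  than 5% divergent transitions, or bulk ESS < 10) the fit is retried once,
  deterministically, with 200 extra warmup iterations and a higher
  acceptance target — the analogue of raising `adapt_delta`. Fits with
  R̂ > 1.01 or any divergences carry a warning either way.

Convergence diagnostics (split R̂, bulk/tail ESS) come from `arviz`.

## Marginal likelihoods and Bayes factors

Evidence is estimated with the iterative Meng–Wong bridge estimator under
the optimal bridge function. The first half of each chain moment-matches a
multivariate-normal proposal; the bridge identity is evaluated on the
second half plus `max(n_eval, 20·dim)` proposal samples (proposal-side
evaluations are cheap, and in ~100-dimensional models they carry the
dominant share of the Monte-Carlo error). The fixed point is iterated to a
relative change below 1e−8 (at most 1000 iterations); when the plain
iteration contracts too slowly — weak posterior/proposal overlap — the same
fixed point is solved directly by Brent's method, bracketed between the
harmonic-mean and importance-sampling estimators, which always enclose it.
The estimator is run on both half-splits and averaged. The reported MC
error combines an independence approximation on the proposal side with an
ESS correction on the posterior side; it is approximate and can
underestimate the error when the sampler has missed posterior mass.

Bayes factors are reported as base-3 logarithms: log₃BF < −1 is at least
moderate evidence for the simpler model, > +1 for the more complex model,
anything between is equivocal (boundaries resolve to "equivocal"; strict
inequalities). The comparison suite fits the four effect/null pairs
({child, adult} × {arousal, valence}), with valence pairs restricted to the
stress and positive conditions.

## The synthetic-data generator

The generator emulates the target study's design: 2 age groups × 3 mood
conditions, two blocks of 210 trials, SOAs drawn uniformly from the seven
levels (a balanced-block option exists; the original counterbalancing is
unreported), an oddball on half the trials (both trial types share the same
accuracy model), and a configurable minority (default 10%) of at-chance
participants who guess on every trial — the population the exclusion filter
exists for. Default ground-truth magnitudes are round values on the scales
seen in comparable texture-learning data — adult asymptote ≈ exp(−2.7) s,
child ≈ exp(−2.1) s, start thresholds around exp(−0.5) s, half-change ≈ 63
trials (slower for adults), between-participant SDs of 0.5 on each
component and 0.2 on log shape — calibrated so that, as in the target
study's sample-size table, essentially all genuine learners pass the
at-chance screen (~88% overall inclusion with the 10% guesser minority).
Condition effects default to zero, matching the study's null result. An
optional block-2 asymptote offset exists for sensitivity studies of the
between-block mood booster; it defaults to zero.

What the generator does *not* emulate: stimulus rendering, reaction times,
attention lapses that vary within session, the late-session performance
decrement visible in the study's raw curves (the analysis handles it by
truncation, which is what the pipeline implements), and mood-rating
dynamics. Passing recovery tests therefore shows that the estimation
machinery is faithful to its own generative assumptions at realistic scale
— not that those assumptions exhaust real behaviour.

## Desk scales used by the test suite

The acceptance-style tests run at reduced scale on one CPU:

* Parameter recovery: 24 learners × 200 trials per age (8 per condition
  cell), zero condition effects, 20 replicates; full model at one chain ×
  (200 warmup + 200 draws). Coverage of zero by the six condition-
  coefficient CIs is the target (≥ 90% of replicate-coefficient pairs).
* Bayes-factor null calibration: 18 learners per age, 10 replicates, four
  comparisons each at 2 chains × (150 + 180) draws; the majority-negative
  check is a sign statistic. At this scale the per-comparison Monte-Carlo
  noise in a log₃BF is of order ±1–2, comparable to the true Occam
  penalty (≈ −1 to −2 per redundant three-coefficient effect block), so
  this is the single most compute-hungry check in the suite and the first
  to lose margin when budgets shrink; larger draw budgets sharpen it
  roughly as 1/√ESS.
* Detection: +1.0 log-unit arousal effect on the asymptote, 24 children
  (8 per condition cell) × 200 trials, 5 replicates; the child arousal
  log₃BF must exceed +1. Asymptote effects are identifiable only where the
  asymptote is approached within the analysis window: children (half-change
  ≈ 45 trials) reach it by mid-session, adults (≈ 90 trials) do not, so an
  adult-only comparison of a true asymptote effect stays equivocal at this
  scale — consistent with the equivocal adult evidence the method reports
  on real data. Between-participant asymptote SD (0.5) makes the realised
  group difference of any one replicate fluctuate around the injected
  value, which is why detection is a majority-of-replicates statistic.
* Recovery/calibration simulations draw learners only (no at-chance
  minority): screening calibration is tested separately, and holding the
  modelled sample at exactly the nominal size keeps replicates comparable.

Production analyses should raise the budgets (≥ 4 chains, ≥ 1000 warmup,
≥ 4000 post-warmup draws for bridge-sampled comparisons, per common
practice).

## Numerical details and edge cases

* Trials are 1-based; the decay kernel uses (t − 1), so `S` is exactly the
  trial-1 log threshold. The half-change identity
  log θ(1 + 10^R) = (S + A)/2 holds to machine precision and is tested.
* The 75% point under nonzero lapse is the closed form
  θ·(−log₂(1 − 0.25/(0.5 − ε)))^{1/β}; it requires ε < 0.25 and is verified
  against bisection. The midpoint parameter θ (not the exact 75% point) is
  the quantity modelled over trials; both are exposed.
* Saturated trials (predicted accuracy within float precision of 1 − ε)
  contribute a clipped log(1 − p) ≥ log(1e−300) and a vanishing gradient
  through the PF, keeping the log density finite on the declared support.
* The decay factor 2^(−(t−1)/10^R) is computed by a per-participant
  recurrence over consecutive trials (exact to ~1e−14 over 200 trials) and
  falls back to direct exponentiation at gaps.
* Screening p-values use the exact binomial survival function; at n = 420
  the attainable test size is slightly below .05 by discreteness, and the
  calibration test accounts for that.
* Empty condition cells cause the affected comparison pair to be skipped
  with a warning rather than failing the suite.

## Known limitations

* The bridge MC error is approximate; with few draws relative to the model
  dimension the log₃BF of a single pair can be off by ±1–2, and rarely more
  if the sampler misses mass in the rate/SD funnels. Raise draw budgets for
  publication-grade comparisons.
* The sampler is single-threaded Python/numba; it is roughly an order of
  magnitude slower per gradient than compiled PPL backends, which is why
  the shipped test scales are modest.
* Asymptotic thresholds are partially extrapolated when the half-change
  time approaches the analysis window; their CIs widen accordingly, and
  asymptote effects are correspondingly hard to detect in slow-learning
  groups.
* The monotonic-valence simplex is weakly identified when the total valence
  coefficient is near zero; its posterior then returns the uniform prior,
  which is the intended behaviour, not a convergence failure.
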