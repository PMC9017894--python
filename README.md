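# oddlearn

Hierarchical Bayesian modelling of trial-by-trial perceptual learning in
texture oddball detection.

## What this is for

In the texture-oddball paradigm an observer views a briefly flashed grid of
oriented lines and reports whether one element was offset; the stimulus
onset asynchrony (SOA) before a pattern mask controls difficulty. Accuracy
over a session improves as the observer's psychometric threshold falls —
perceptual learning. `oddlearn` is for researchers who want to model that
improvement *continuously, trial by trial*, rather than by block averages,
and to ask whether experimental manipulations (here: mood inductions
crossed over arousal and valence in children and adults) changed any
component of learning.

The observation model is Bernoulli accuracy through a chance-floored Quick
(Weibull) psychometric function whose threshold decays exponentially with
trial number:

    P(correct | SOA x, trial t) = ½ + (½ − ε)(1 − 2^{−(x/θ(t))^β}),
    log θ(t) = A + (S − A) · 2^{−(t−1)/10^R},

so each participant has a starting log-threshold *S*, an asymptotic
log-threshold *A*, a half-change time 10^R (trials), and a PF shape β.
Components receive group fixed effects — age (±½), an arousal contrast
(±½), and a *monotonic* valence effect (stress < control < positive,
parameterised by a Dirichlet simplex) — plus by-participant random effects,
estimated jointly by MCMC (a built-in NUTS sampler with analytic
gradients). Competing models are compared by bridge-sampling marginal
likelihoods, reported as base-3 log Bayes factors (±1 = moderate
evidence).

The package also ships the surrounding pipeline: a synthetic-experiment
generator with known ground truth (2 age groups × 3 conditions, 2 × 210
trials, SOAs from {15, 30, 60, 90, 120, 300, 500} ms, plus an at-chance
minority), exact-binomial screening of at-chance participants, truncation
to the first 200 trials, coefficient tables with 95% credible intervals,
and the four effect-vs-null comparisons per age × affective dimension.

## Worked example

```python
import numpy as np
from oddlearn import (DesignSpec, GroundTruth, simulate_experiment,
                      exclude_at_chance, apply_screening, truncate_trials)
from oddlearn.model import LearningModel, ModelSpec

# a small experiment with known truth: no condition effects,
# adults asymptote 0.3 log-units lower than the grand mean
design = DesignSpec(n_per_cell=4, n_blocks=2, trials_per_block=105, seed=42)
truth = GroundTruth()              # study-shaped defaults, zero condition effects
records, participants = simulate_experiment(design, truth)

screening = exclude_at_chance(records)          # one-tailed exact binomial, p < .05
modelled = truncate_trials(apply_screening(records, screening), 200)
print(f"included {screening.included.sum()} of {len(screening)} participants")

model = LearningModel(modelled, ModelSpec.full())
result = model.fit(draws=250, warmup=250, chains=2, seed=1)
print(result.summary().round(3))
print(result.diagnostics())
```

Output (abridged):

```
included 23 of 24 participants
                      Estimate  lower 95% CI  upper 95% CI  reliable
Asym: Intercept         -2.816        -3.670        -2.131      True
Asym: age                0.024        -1.148         1.282     False
Asym: arousal           -0.017        -1.118         0.825     False
...
Rate: Intercept          2.045         1.499         2.500      True
Rate: arousal            0.674         0.028         1.336      True
...
PF shape: Intercept      0.942         0.727         1.159      True
{'max_rhat': 1.038..., 'min_ess_bulk': 67.3..., 'min_ess_tail': 65.6..., 'divergences': 0}
```

Reading it: the asymptote intercept −2.82 log-seconds is a cross-group
asymptotic threshold of ≈ 60 ms (truth −2.4, inside the CI); the rate
intercept 2.05 is a half-change time of 10^2.05 ≈ 112 trials (truth 63,
inside the CI — rate is the hardest component to pin down in a single
short session). Condition rows are contrasts on the log scale and
"reliable" flags CIs excluding zero. Eleven of the twelve truly-zero
condition contrasts are correctly unflagged; `Rate: arousal` is flagged
with its CI barely clearing zero — exactly the ~5% false-positive risk a
95%-CI criterion carries, and the reason model comparison backs up the CI
table. `PF shape: Intercept` is the log Weibull shape (exp(0.94) ≈ 2.6;
truth 3.0).

Bayes-factor comparisons and the full pipeline:

```python
from oddlearn.bridge import run_comparison_suite
comparisons, fits = run_comparison_suite(modelled, draws=250, warmup=250,
                                         chains=2, seed=2)
for c in comparisons:
    print(f"{c.label}: log3(BF) = {c.log3_bf:+.2f} -> {c.verdict}")
```

```
child-arousal: log3(BF) = +0.18 -> equivocal
child-valence: log3(BF) = -1.71 -> supports-simpler
adult-arousal: log3(BF) = -1.47 -> supports-simpler
adult-valence: log3(BF) = -0.60 -> equivocal
```

On this zero-effect dataset all four comparisons refuse to endorse the
effect models: two fall past the moderate-evidence boundary of −1 for the
simpler model and two are equivocal — in particular the bridge-sampled
evidence does not reproduce the spurious `Rate: arousal` flag from the CI
table.

The same pipeline is scriptable from the shell:

```bash
oddlearn run --seed 7 --out runs/demo          # simulate→screen→fit→compare→report
oddlearn simulate --n-per-cell 24 --out data/  # just the generator
oddlearn screen --input data/trials.csv --out screening.csv
```

`run` writes trial and ground-truth CSVs, screening results, a sample-size
table, one coefficient CSV per fitted model, a comparisons JSON with
verdicts, and a `run_manifest.json` capturing config, seeds, input hashes
and stage timings; re-running with the same manifest settings reproduces
the outputs.

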