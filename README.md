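# hedoseek

Simulation and hierarchical Bayesian analysis of two lottery-prediction
information-seeking experiments: a two-source choice task in which sources
("psychics") vary in the accuracy and positivity of five example predictions,
and a single-source belief-rating task quantifying asymmetric belief updates.

The package provides:

- **`task_design`** — combinatorics of feasible `(nAcc, nPos)` source
  profiles (56 admissible two-source trial configurations), trial validation,
  and randomised blocked schedules for both experiments.
- **`choice_models`** — four softmax choice models (accuracy+positivity,
  accuracy only, positivity only, positivity-as-tiebreak) as likelihoods and
  generative samplers.
- **`belief_models`** — signed belief-update quantification relative to the
  50-point indifference level, and the Gaussian update models (full /
  no-positivity) with a multiplicative win-direction asymmetry.
- **`inference`** — hierarchical Bayesian posterior sampling for all six
  models (non-centred parameterisation, bounded inverse temperature, the
  published weakly-informative hyperpriors) via a built-in No-U-Turn sampler
  with dual-averaging step-size and diagonal mass adaptation; split-R-hat /
  ESS / divergence diagnostics via ArviZ.
- **`model_comparison`** — leave-one-participant-out elpd (exact refit or
  truncated importance sampling), WAIC, Bayesian stacking weights,
  best-model proportions, posterior predictive checks.
- **`recovery_rope`** — model- and parameter-recovery analyses, HDI
  computation, and ROPE construction (bound = 0.1 · SD of updates / maximum
  predictor change) with containment decisions.
- **`synthetic_cohort`** — reproducible synthetic cohorts for both
  experiments (the human data are available only on request).
- **`pipeline` / `cli`** — seed-controlled simulate → fit → compare →
  rope orchestration and descriptive summaries.

## CLI

```sh
hedoseek design   --experiment 1 --seed 1 --out schedule.csv
hedoseek simulate --experiment 1 --model accpos --n 20 --seed 1 --out sim/
hedoseek fit      --model accpos --data sim/dataset.csv --chains 4 \
                  --warmup 1500 --draws 5000 --seed 1 --out posterior/
hedoseek compare  --models accpos,acc,pos,tiebreak --data sim/dataset.csv \
                  --method tis --seed 1
hedoseek recover  --kind model --n 15 --sims 2 --seed 1
hedoseek rope     --data sim2/dataset.csv --seed 1
hedoseek report   --data sim/dataset.csv
hedoseek demo     --experiment 1 --out demo_run --seed 1
```

Paper-scale sampling (4 chains, 1500 warm-up, 5000 draws) is the CLI
default; tests use smaller, documented configurations.

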