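# temporalchoice

A tested Python implementation of an intertemporal-choice analysis chain for
a two-group (rTPJ vs. vertex stimulation) × two-session (pre/post) study
design, operating entirely on synthetic data generated by the package
itself. It covers:

* **Discount models** (`temporalchoice.discount`) — quasi-hyperbolic
  (β·δ^delay), one-parameter hyperbolic and generalized hyperbolic
  subjective-value functions, a softmax choice rule against a fixed
  10-CHF smaller-sooner option, Bernoulli log-likelihoods with pointwise
  output, and the normalized area under the generalized hyperbolic
  discount curve.
* **Synthetic cohort** (`temporalchoice.cohort`) — the fully crossed
  9 reward × 9 delay choice design (81 combinations, repeated twice per
  session, 81 trials per run), the 2×2×2 mental time-travel design
  (72 events per session, 36 per run), log-normal participant parameters,
  a configurable multiplicative post-session stimulation effect on the
  scaling parameter *s*, and a log-RT generator with a
  group × session × event-time interaction (default coefficient 0.045).
* **Bayesian inference** (`temporalchoice.bayes`) — adaptive random-walk
  Metropolis on unconstrained parameters (2 chains × 4,000 samples,
  1,000 burn-in by default), split R-hat diagnostics, pre-session
  posteriors moment-matched into inflated post-session priors, a
  from-scratch PSIS-LOO implementation (probability-weighted-moments
  generalized Pareto tail fit), an exact refit-LOO oracle, and a
  parameter-recovery harness.
* **Group statistics** (`temporalchoice.groupstats`) — Mann–Whitney U via
  the tie-corrected normal approximation (continuity correction behind a
  flag, off by default), effect size r = |Z|/√N, normal tail
  probabilities, baseline normalization, Bonferroni correction and
  Spearman correlation with a t-approximation p-value.
* **Time-travel RT contrasts** (`temporalchoice.timetravel`) — a two-stage
  future-minus-past log-RT contrast analysis whose group-mean difference
  equals the indicator-coded fixed-effects regression interaction
  coefficient exactly in balanced designs, plus the cross-task Spearman
  correlation with changes in *s*.
* **ROI GLM / PPI** (`temporalchoice.roiglm`) — double-gamma HRF
  convolution, mean-centered parametric value modulators, discrete-cosine
  high-pass filtering (128 s cutoff), OLS with contrast evaluation, PPI
  regressors formed by direct multiplication of the filtered seed series
  with the psychological regressor, and a coupled seed/target BOLD
  simulator for recovery testing.
* **Pipeline + CLI** (`temporalchoice.pipeline`, `temporalchoice.cli`) —
  an end-to-end seeded, cached, resumable run producing a consolidated
  JSON/text report.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (design counts,
effect-size arithmetic, model-comparison direction, parameter recovery,
oracle equivalences, type-I calibration, PPI direction). The full suite
takes a few minutes on one CPU; the simulation-heavy tests run at reduced
scale with frozen seeds.

## CLI

```sh
temporalchoice simulate --seed 1 --out run/cohort
temporalchoice fit --model generalized --choices run/cohort/choices.csv \
    --session pre --out run/fits
temporalchoice fit --model generalized --choices run/cohort/choices.csv \
    --session post --priors chained:run/fits --out run/fits
temporalchoice compare --fits run/fits
temporalchoice group-stats --fits run/fits --cohort run/cohort --measure s
temporalchoice rt-analysis --rts run/cohort/rts.csv --out run/contrasts.csv
temporalchoice correlate --contrasts run/contrasts.csv --fits run/fits
temporalchoice ppi-demo --replicates 500 --seed 1 --out run/ppi
temporalchoice run-all --seed 1 --fast --out run/full   # or --paper-scale
```

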