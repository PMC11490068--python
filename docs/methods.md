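# Methods

## Model and assumptions

`duoread` models a reader's binary recall decision on one examination as
a Bernoulli draw whose logit is the sum of a fixed reader effect and a
latent case effect shared by everyone who reads that examination.
Cancer-free and cancer examinations get completely separate models
(effects `r_j−`/`r_j+`, case scales `sigma_C−`/`sigma_C+`): in screening
the negative pool is orders of magnitude larger than the positive pool
and there is no assumed link between a reader's specificity and
sensitivity mechanisms.  The case effect has mean zero and normal
distribution; it is what correlates the two readers of a pair, so pair
disagreement counts identify `sigma_C` while single-reader counts alone
cannot (any `(r, sigma)` combination matching the marginal rate would be
equivalent — hence a fit without pair data is refused as not
identifiable).

Consequences of the assumptions worth keeping in mind:

- The model has no per-case covariates; "difficulty" is unidimensional
  and acts identically on all readers.
- Reader behavior is stationary: no learning, fatigue, or batch-order
  effects.
- Arbitration/consensus after a discordant pair is *not* modeled; the
  pair endpoint uses the any-reader-flags rule, under which the pair's
  recall probability is `p = a1 + a2 − a1·a2`.

## Marginalization and fitting

Marginal rates are expectations of the logistic conditional
probabilities over the case-effect distribution, computed by Monte Carlo
integration.  The default sample size is 1,000,000, at which the
coefficient of variation of a marginal-rate estimate at a representative
screening operating point (reader effect −3, case SD 1.5) is about 0.12%
(measured over 50 seeds by `scripts/acceptance.py`); `sigma = 0`
short-circuits to the exact logistic value.

The likelihood is the standard binomial form
`A ln a + (K − A) ln(1 − a)` summed over readers plus
`D ln d + (K − D) ln(1 − d)` summed over observed pairs, per case class,
with the parameter-free log-factorial constant dropped.  Numerical
choices:

- **Common random numbers.**  One standard-normal case-effect sample per
  case class is drawn at the start of a fit (independent streams for the
  two classes, spawned from the Monte-Carlo seed) and reused for every
  likelihood evaluation.  This makes the objective deterministic, which a
  derivative-free optimizer requires; refitting with a different stream
  moves recovered rates by less than the combined Monte-Carlo standard
  error (asserted in tests).
- **Powell's method** with fractional tolerance `ftol = 1e-4` optimizes
  `(r_1..r_J, log sigma)` jointly per class.  `sigma` lives on the log
  scale to stay positive; initialization takes each `r_j` at the logit of
  its Agresti–Coull adjusted direct rate and `sigma = 1`.  The iterate
  log is kept and must be monotonically non-increasing.
- **Clipping vs signalling.**  Inside the optimizer marginal rates are
  clipped to `[1e-12, 1 − 1e-12]` so a wild trial step cannot produce
  `log 0`; the public likelihood function instead raises a
  degenerate-likelihood error when a rate hits exactly 0 or 1, because a
  user evaluating at such parameters should hear about it.
- **Direct estimates** use the Agresti–Coull adjustment
  (`z^2/2` pseudo-successes, `z^2` pseudo-trials) with intervals clipped
  to `[0, 1]`; a reader or pair with zero trials in a class is reported
  as missing, never fabricated.

Eligibility filters applied before fitting mirror registry practice:
every reader needs at least one true positive and one false positive,
abnormal calls must not equal reads in either class, and pairs with
fewer than 17 jointly read positive examinations are dropped (the
threshold is configurable; 17 is the value at which the remaining pairs
in the motivating registries satisfied the preceding conditions, and it
need not generalize to other data).

## Synthetic data

The generator exists because real double-reading registry extracts are
confidential.  It emulates: exactly two readers per exam; prevalence of a
few per 1,000 (default 0.006); heterogeneous reader operating points from
a bivariate normal on the logit scale with positive TPR–FPR association
(default correlation 0.8, means −3.3/1.0 and SDs 0.3/0.5, giving mean
individual FPR ≈ 4–5% and TPR ≈ 65–70%, magnitude-realistic for organized
mammography screening); a shared case effect per exam with independent
streams for the two classes; and sparse pair coverage via either a
`chained` scheme (reader *i* with *i*+1, wrapping — guarantees
identifiability with few pairs) or `random_rotation` (pool reshuffled
into pairs every block of exams — registry-style sparsity).

What it does **not** emulate: lesion-level detail, reader experience or
volume covariates, interval-cancer timing, drift over time, and any
dependence between a case's difficulty and its probability of being
cancer.  Tests passing on this generator therefore show that the
estimator and simulator are correct *under the model's own assumptions*,
not that the model captures every feature of real readers.

## Pairing simulation

Each simulated day draws its reader pool (without replacement) from a
stream that depends only on the master seed and day index; the random-
pairing stream is separate, so all seven strategies face identical days,
pools, and examinations — asserted by checksumming the case-status and
case-effect streams.  Pairing metrics are the *modeled* marginal TPR/FPR.
The composite slope is recomputed per day over the day's 16-reader pool
(pairing operates within the pool, so the pool-level regression is the
coherent choice; a population-level slope could be supplied instead by
precomputing scores).  Batches are assigned to pairs round-robin, so
loads differ by at most one batch.

Group endpoints average the analytic probabilities (`p` for pairs, `a`
for individual reading).  Bernoulli-sampled 0/1 decisions are provided
separately (`sample_binary_outcomes`) for TP/FP counts and the
concordant-positive / concordant-negative / discordant classification;
the decision stream is shared across strategies so count differences are
paired comparisons.  A stratum with no examinations yields NaN, never a
fabricated rate.

Bootstrap intervals resample examinations with replacement within each
case-status stratum (TPR and FPR are stratum means) and take percentile
intervals at the Bonferroni-adjusted level — 6 comparisons for the six
non-random strategies against random, 7 for the paired-versus-individual
contrasts.  Unadjusted 95% intervals achieve 93–95% empirical coverage in
the package's 500-replicate calibration study.

## Problem sizes used in the test suite

Simulation-backed tests run at deliberately reduced scale, chosen so each
check retains clear statistical power: the parameter-recovery harness
uses 10 readers with ~20,000 negative and ~200 positive reads each and a
20,000-sample Monte-Carlo integral; the directional study uses 200
replicates of a 30-day × 1,000-exam schedule over a 40-reader population
with FPR-effect SD 0.4; the coverage study uses 500 replicates of 300
exams per stratum.  The full-scale defaults (10^6 Monte-Carlo samples,
365 × 4,000 schedule) remain the package defaults.

In the directional study the population's positive-case heterogeneity
(SD 0.3) is generated independently of the negative-case effects.  This
isolates the mechanism under test: pairing on FPR then has no systematic
relationship to TPR, so the claim "similar-FPR pairing lowers group FPR
while TPR is unchanged" can be tested sharply (sign test for the FPR
direction; a one-sided t-test at the 1% level must not detect a negative
mean TPR shift).  With strongly correlated axes, FPR-similar pairing is
partially TPR-similar pairing and genuinely trades away some sensitivity;
that regime is available through the generator's correlation parameter.

## Known limitations

- Marginal TPR recovery for an individual reader is limited by the
  positive-read volume: with ~200 positive reads the binomial noise floor
  (SD ≈ 0.034) is comparable to realistic between-reader TPR spread, so
  correlations between true and recovered TPR plateau around 0.9 at that
  volume regardless of the optimizer.  FPR recovery, with tens of
  thousands of negative reads, does not suffer this.
- No standard errors are produced for the fitted parameters themselves
  (only for rates via bootstrap in the simulator).
- The seven strategies pair greedily within a day's pool; no attempt is
  made to optimize pairing across days or to search beyond these rules.
- Powell's method finds a local optimum; with the direct-estimate
  initialization and common random numbers this has been stable in
  practice, but a pathological dataset could require restarts, which are
  not automated.
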