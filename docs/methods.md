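# Methods

## Phonotactic scoring

Positional biphone probabilities are token statistics weighted by log10
frequency: the weight of biphone *b* at position *p* is the summed log10
token frequency of words carrying *b* at *p*, normalized by the summed
log10 frequency of all words long enough to have any biphone at *p*.
Consequences that the implementation embraces rather than papers over:

- Probabilities at each position sum to one (asserted to 1e-9), because
  every sufficiently long word carries exactly one biphone per position.
- `log10(1) = 0`: hapax words legally contribute zero weight. No smoothing
  is applied; unattested biphones score exactly 0 and are flagged.
- The statistic is not invariant to rescaling all frequencies, so the table
  exposes its numerators and denominators and tests assert exactly
  recomputed values instead of invariance.
- Homophones are distinct entries and both contribute (token statistic).

Word-level PP defaults to the **sum** of the word's positional biphone
probabilities (the convention of the positional-statistics literature); a
mean aggregation is available. Only set means are externally anchored —
the per-word aggregation behind the published stimulus table cannot be
determined from its printed values alone.

## Pseudoword search and recombination

Candidates are chains of table biphones matching a C/V template (default
CVCV): the biphone at position *p* must end with the segment the biphone at
*p*+1 starts with. Real lexicon words are excluded (novelty is exact
phoneme-sequence membership; orthography is ignored). Ranking is by
descending PP with lexicographic tie-break, so the search is deterministic.

Set selection is greedy down the ranking under greedy-checkable diversity
constraints: a cap on shared (position, biphone) pairs between chosen words
and a cap on onset reuse. The pipeline defaults to `max_shared_biphones=0`;
without a diversity constraint the top of the ranking is dominated by
near-duplicates built from the same two or three syllables, whose
recombination space is too impoverished to form a matched second set.

"Recombination" is interpreted at the CV-syllable level — the published
PP−/PP+ word lists pair up exactly this way, with syllables reappearing in
switched positions — and selects the highest-PP novel rearrangements whose
mean is strictly below the PP+ mean and at or above a floor (default 0.75
of the PP+ mean). A biphone-level mode (chains restricted to the PP+ sets'
positional biphones) is available behind a flag; its candidate space is
considerably smaller. A degenerate, fully symmetric table makes the
strict-decrease requirement unsatisfiable, which is reported as an error
rather than silently returning an equal-PP set.

## Design generation

The published counts (each of 6 labels per set seen 6 times in 18 two-pair
trials, every label contrasted with the other 5) do not uniquely determine
the pairing schedule. We use the minimal construction satisfying both: all
C(6,2) = 15 distinct pairings once, plus one seeded perfect matching (3
pairings repeated). This yields the co-occurrence signature diagonal 6,
within-set off-diagonal ≤ 2, cross-set 0 — a 3:1 separability ratio that
guarantees an ideal co-occurrence learner is always correct, and which the
validator checks on every generated design.

Interleaving is a seeded random order with at most 2 consecutive same-set
trials (strict alternation available). Word play-order and object side are
randomized with an exact-balance constraint: the first-played word's
referent appears on the left in half the trials ±1, and the validator
reports the resulting point-biserial correlation. Test foils are drawn from
the 5 same-set objects by seeded greedy count-balancing (appearance spread
≤ 1 within a set, with restart if violated); target corners are balanced
exactly across the four positions. Timing metadata per training trial is
950 + 696 + 700 + 696 + 950 ms ≈ 4 s, with a 1 s fixation carried as
metadata only.

Counterbalancing: version A pairs words and objects by a seeded shuffle;
version B reuses A's draw but swaps the two sets' object blocks, so every
word keeps its set, every object changes set, and A and B share no pair.

## Simulated learners

Neither simulator is a claim about human cognition; they exist so the
pipeline is testable end to end without data collection.

- **Associative learner**: accumulates the word×object co-occurrence count
  matrix over training, then answers each 4AFC probe by a softmax over the
  four displayed objects' counts (temperature 0 = argmax with seeded
  tie-break); a lapse rate mixes in uniform guessing.
- **Generative GLMM learner**: the exact generative counterpart of the
  analysis model, so parameter recovery is well-posed:
  P(correct) = expit(logit(.25) + β₀ + δ·[PP+] + u_participant + u_stimulus),
  with incorrect choices uniform over the three foils (the analysis model
  only sees correct/incorrect).

Default generative parameters emulate the published full-dataset fit
(β₀ = log 7.61 ≈ 2.03, δ = log 1.19 ≈ 0.17, τ_participant = √2.35 ≈ 1.53,
τ_stimulus = √0.21 ≈ 0.46), which puts simulated mean accuracy near the
study's ~66%.

Reaction times are lognormal (median ≈ 1.1 s, log-SD 0.3) with a uniform
far-tail contamination component on 15–40 s at rate 0.02 — the share of
trials the published analysis excluded. The contamination floor of 15 s is
deliberately above any achievable 3-SD threshold for these settings, so
the exclusion rule's recall/precision can be tested exactly; real lapses
are of course not guaranteed to be so separable. The 3-SD rule on the raw
(skewed) lognormal also removes a small number of legitimate slow trials
(~1% in practice), which is a property of the rule, not a bug.

What the generator does **not** emulate: within-test learning across the
two repetitions, fatigue or order effects, stimulus-specific
perceptual confusability, and any dependence of RT on correctness. Tests
passing on this synthetic data certify the pipeline's arithmetic and
statistical calibration, not conclusions about human learners.

## Analysis

RT exclusion is a single pass removing trials more than k = 3 sample SDs
from the mean. The default scope is global within each dataset variant;
a per-participant scope is provided, since pooling is ambiguous in verbal
descriptions of this rule. Exclusion runs independently for the full
(both test repetitions) and halved (first repetition only) variants.

Chance enters the linear predictor as a fixed offset logit(0.25) = log(1/3)
with PP− as the reference level — the only reading under which the
intercept's odds ratio is interpretable as above-chance odds for PP−, and
the product of the intercept and PP+ odds ratios as the PP+ odds above
chance.

**Frequentist fit** (`cswlkit.glmm`): a compact Laplace-approximation
fitter for binomial mixed models with independent random intercepts,
written for this pipeline so the offset, crossed grouping, and speed
requirements of the simulation studies (hundreds of refits) are fully
under control. The random-effect mode is found by damped Newton, the
marginal deviance maximized by L-BFGS-B over (β, log τ), and Wald CIs come
from the numeric Hessian of the marginal deviance in β with τ fixed at its
estimate — the same algorithm family and conventions as lme4's default
`glmer`, against which the test suite cross-checks one fit (agreement to
~1e-3 on coefficients and SEs). Complete separation and optimizer failure
are flagged, not fatal. τ is bounded in [1e-4, 20] on the SD scale; fits
at the lower bound are ordinary logistic regressions, as expected when the
generating heterogeneity is zero.

**Bayesian fit** (`cswlkit.bayes`): the maximal specification — random
participant intercepts plus a stimulus-within-participant deviation with
one shared SD (the practical reading of per-participant stimulus slopes;
slope correlations are not modeled). Priors are weakly informative:
β ~ N(0, 2.5²), τ ~ HalfNormal(2.5). Sampling is adaptive
Metropolis-within-Gibbs on a non-centered parameterization: vectorized
element-wise random-walk updates for the standardized random effects
(valid because they are conditionally independent given the rest), a joint
walk for β, scalar walks for the log-SDs; proposal scales adapt during
warmup toward standard acceptance targets. Four chains; split-chain R-hat
(via arviz) is reported per parameter, with the convergence flag set at
the strict 1.01 threshold — short runs will honestly report
non-convergence while still giving usable medians. With only one
observation per participant×stimulus cell (the halved variant), the cell
SD is weakly identified and the posterior leans on its prior; the same
behavior is visible in published maximal-model fits of such designs.

ICC uses the latent-scale logistic residual variance π²/3 ≈ 3.29;
marginal/conditional R² use the fixed-effect variance var(Xβ) computed
over the observed design. Bootstrap accuracy summaries resample
participants with replacement (percentile 95% intervals, seeded).
p-values are not reported by default.

Power for the one-sample t-test against 0.25 is exact noncentral-t
(statsmodels), with noncentrality d·√n.

## Problem sizes and numerical choices

- Calibration experiments (shared by tests and the acceptance script):
  ideal-learner ceiling over 100 design seeds; null-intercept coverage over
  500 replicates of 12-participant cohorts; parameter recovery over 100
  cohorts of 60 participants at β₀ = 1, δ = 0.5, τ_p = 1, τ_s = 0.3. These
  sizes give Monte-Carlo SEs of ~1% on coverage and ~0.02 logits on bias,
  small enough to detect miscalibration that matters.
- All randomness flows from explicit seeds; per-stage sub-seeds are fanned
  out of the global seed by hashing, and identical configuration + seed
  reproduces every artifact byte-for-byte (manifests record checksums).
- Ranking and selection ties break lexicographically; design sampling uses
  bounded retry loops with seeded generators and reports infeasibility as
  errors instead of looping forever.

## Known limitations

- The bundled lexicon is synthetic (Zipfian frequencies over a CV
  language); real-corpus biphone statistics are richer, and the achievable
  PP contrast between matched sets depends on the corpus.
- The frequentist fitter supports independent random intercepts only — the
  specification the published frequentist analysis converged to; random
  slopes are the Bayesian model's job here.
- The Metropolis-within-Gibbs sampler trades sampling efficiency for
  transparency; for large cohorts expect to raise the draw budget to reach
  R-hat < 1.01.
- Observed-data replication of the published odds ratios requires the
  original participant responses, which this package does not ship; its
  response-table schema accepts such data if supplied.
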