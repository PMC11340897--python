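# Methods

This note documents the statistical procedures `vocabrank` implements, the
assumptions behind its synthetic-rater generator, and the numerical choices
made where the design was genuinely open.

## Implied rankings and tie conventions

A participant rating n phrases on a 0–100 slider implies a *weak order*: the
midrank transform of the negated ratings, so a higher rating is a better
(numerically smaller) rank and equal ratings share an averaged rank. The
package applies one tie policy everywhere:

- a tied order **never** counts as matching the strict intended ranking,
  even if no rated pair contradicts it — matching requires the participant
  to separate every phrase as intended (the conservative reading for a
  "correct ranking" count);
- in Kendall's distance, a phrase pair tied in exactly one of the two orders
  contributes ½ a discordance (the tau-b-style convention), which keeps the
  distance symmetric and bounded by n(n−1)/2;
- in the concordance matrix, a tie group of t phrases sharing midrank r
  occupies the t consecutive integer positions centred on r, each member
  contributing 1/t of a participant to each position. This preserves row
  *and* column sums, so the matrix is doubly stochastic up to rounding.

Integer slider data make ties common, so the policy materially affects the
matched counts; any comparison against an analysis with a different tie rule
should reconcile this first.

## Sison–Glaz simultaneous intervals

Matched/unmatched proportions are interval-estimated with the Sison–Glaz
construction for multinomial proportions. The simultaneous coverage of
"every count within ±c of its observation" is estimated by representing the
multinomial as independent Poissons conditioned on the total: each cell uses
the first four central moments of a doubly truncated Poisson, combined
through an Edgeworth expansion for the conditioning event. The
implementation takes c* as the **largest integer whose estimated coverage
falls below 1−α**, interpolates γ = (1−α−ν(c*)) / (ν(c*+1)−ν(c*)), and
returns [p̂ᵢ − c*/N, p̂ᵢ + c*/N + 2γ/N] clamped to [0, 1]. Published
variants differ in whether c* or c*+1 enters the interval; the convention
above is the original one, and it is the variant whose two-category
intervals for 59/301 and 188/301 round to the printed [15%, 24%] and
[57%, 68%]. Empirical simultaneous coverage is property-tested
(k = 3, N = 300, 2,000 multinomial replicates, threshold 0.93 at nominal
0.95 to absorb Monte-Carlo error).

The operation accepts any k ≥ 2. The pipeline applies it to the
two-category (matched, unmatched) counts; a full multinomial over distinct
rankings is possible with the same function and gives wider intervals.

## McNemar machinery

The paired vocabulary comparison conditions on the discordant total
m = b + c, under which b ~ Binomial(m, ½) given marginal homogeneity. The
exact p doubles the smaller tail (capped at 1); the mid-p variant subtracts
the observed outcome's point probability once before capping, which removes
much of the exact test's conservatism (mid-p ≤ exact p is verified
exhaustively for m ≤ 50). The conditional odds ratio is b/c; its CI treats
b as Binomial(m, π), computes the mid-p Clopper–Pearson interval for π by
bisection (tolerance 1e−10), and maps through OR = π/(1−π). c = 0 yields an
infinite point/upper bound, flagged in the method tag; b + c = 0 leaves the
odds ratio undefined (the comparison object carries `None`). No
multiple-testing correction is applied across dimensions — two paired tests
are reported as-is, and this is deliberate.

## Quantiles, bootstrap, densities

Quantiles use linear interpolation of order statistics (NumPy's default
rule). The rule matters at the margins: published quartile tables can shift
by a point under other conventions, so the choice is fixed and stated.
Median CIs use the percentile bootstrap (default 10,000 resamples, seeded;
coverage of the nominal 95% interval is verified empirically to land in
[0.90, 0.99] over 500 simulated cohorts of n = 301). Kernel density
profiles use a Gaussian kernel with Silverman's rule-of-thumb bandwidth
0.9·min(sd, IQR/1.34)·n^(−1/5) and **boundary reflection** at 0 and 100 —
reflection was chosen over truncate-and-renormalise because slider data pile
up near the scale ends and reflection keeps the estimate's integral at one
without inflating interior mass.

## The synthetic-rater generator

The generator emulates a repeated-measures slider study: every participant
rates all 21 phrases of four vocabulary × dimension blocks.

Generative model, per participant i and phrase j:

- a participant-level *coherence shift* sᵢ ~ Normal(0, coherence_sd) shared
  by all of i's responses (default SD **3** rating points) — this is what
  makes a person's implied ranking more stable than independent draws would
  be;
- with probability lapse_prob (default **0.01**) the response is a uniform
  draw on [0, 100] (attentional lapse);
- otherwise rᵢⱼ = 100·Beta(aⱼ, bⱼ) + sᵢ + Normal(0, noise_sd) with
  per-response jitter SD **4**;
- responses are rounded to integers and clamped to [0, 100] (a slider
  granularity assumption; the scale's bounded support is why the marginal
  family is a scaled Beta).

Cohort defaults mirror the emulated study's conditions: 461 respondents,
attention-failure probability 156/461, overtime (> 30 min) probability
12/461, nobody incomplete or under 5 minutes. Durations are uniform on
(6, 28) minutes, or (31, 60) for overtime cases. The noise SDs are the
package's own choice (no empirical per-rater noise decomposition is
published): 3 and 4 points give a combined per-response SD of 5, small
against the ≥ 10-point spacing of the well-separated vocabulary and
comparable to the 1–2-point spacing of the overlapping one, which reproduces
the qualitative contrast between the two.

**Calibration.** `calibrate_scaled_beta` fits (a, b) by least squares on the
scaled-Beta quantile function at (0.25, 0.5, 0.75) against target quartiles
(Nelder-Mead on log-shapes from a moment-matching start; deterministic).
A two-parameter Beta cannot reproduce every asymmetric quartile triplet:
across the 21 published triplets the worst fit error is ~2.0 points
(a sharply asymmetric mid-scale phrase), within the documented tolerance of
2.5; most phrases fit within 1 point. The default study configuration goes
one step further: because the published quartiles describe *observed*
responses — noise included — `default_config` calibrates each Beta so that
the **marginal of the full generative model** (Beta + coherence shift +
jitter + lapse mixture, computed by numeric convolution) hits the targets,
minimising the worst absolute quartile gap (Chebyshev objective, since the
generator's contract is a bound on the largest deviation). With this
deconvolving calibration, simulated cohorts of 300 reproduce all 21 phrase
quartiles within ±3 points.

**What the generator does not model.** Real response distributions show
multimodality and end-digit clustering that a single Beta cannot produce;
presentation-order effects, the between-block structure, and any
participant × phrase interaction beyond the shared shift are absent. Tests
passing on synthetic cohorts therefore validate the *pipeline's arithmetic
and its qualitative contrasts* (overlapping phrases → low matched share,
monotone degradation with noise), not distributional fine structure of real
raters.

## Exclusion screen

Criteria run in the fixed narrative order attention → overtime → incomplete
→ too-fast; a participant is attributed to the first criterion they fail.
Membership of the retained set is order-invariant (property-tested); only
the attribution differs. "Incomplete" means fewer responses than the
expected statement count, inferred from the table when not configured.
Participants with unknown duration are never excluded on timing grounds —
deposited data may arrive without timing columns, and silently dropping
everyone would be worse than skipping the criterion.

## Problem sizes and determinism

Default analyses use 10,000 bootstrap resamples; verification suites use
scaled-down but statistically adequate sizes chosen for convergence of the
checked property (500 cohorts for bootstrap coverage, 2,000 replicates for
simultaneous-coverage estimation, 150–300 raters per simulated block, seed
grids of three for monotonicity checks). Every random stage takes an
explicit seed; report tables are byte-identical across re-runs of the same
configuration (the JSON manifest carries a wall-clock timestamp; the CSV
tables do not).

## Known limitations

- Distinct-ranking counts depend on the tie policy; comparing them across
  vocabularies of different n is flagged rather than normalised away.
- The Sison–Glaz coverage estimate is asymptotic in character; for very
  small N or extreme proportions the empirical coverage can drift below
  nominal (the property test bounds this at k = 3, N = 300).
- The mid-p odds-ratio interval is not exact-coverage by construction; it
  trades guaranteed ≥ 95% coverage for near-nominal average coverage.
- The generator's marginal calibration residual (≤ ~1.5 points analytic,
  ≤ 3 with sampling noise at n = 300) is a family limitation, not a fitting
  failure; a mixture model would be needed to do better.
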