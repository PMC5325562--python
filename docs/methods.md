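# Methods

This note documents the models, numerical choices and limitations of
`adragree`: what each module computes, the design decisions taken where the
problem left room, and what the synthetic generator does and does not
emulate.

## The flowchart engine

The LCAT is encoded as data (`adragree/data/lcat.yaml`): ten dichotomous
questions, each with a positive and a negative successor that is either
another question or one of the four ordinal outcome categories.  The loader
enforces the structural invariants — every node reachable from Q1, no
cycles, no degenerate node whose two branches coincide — and the topology
validator reports three further properties of the packaged chart that the
transcription must satisfy:

* the unrolled decision tree has exactly **36 root-to-outcome paths**
  (definite 12, probable 8, possible 12, unlikely 4);
* a *definite* outcome is reachable **only** through a positive answer on
  Q5a (the patient previously experienced the same event with the same
  drug) or Q5b (positive rechallenge).  Q6 — "is the event a previously
  described reaction to this drug?" — leads to *probable* when positive and
  *possible* when negative; it is drug-level knowledge, distinct from the
  patient-level past history of Q5a;
* a negative answer on Q1 (temporal relationship) is immediately terminal
  (*unlikely*), and Q2b is reached only after a negative Q2a.

Transcription provenance: the figure's full edge set is not stated in prose
anywhere, so the packaged chart was reconstructed by treating the reference
study's per-question response totals as flow-conservation constraints (for
example, Q4b's 31 responses equal Q4a's 31 negatives exactly, and Q6's 30
responses equal Q5b's 30 negatives), then checked against the path count and
the outcome marginals (29 positive Q6 answers alongside 29 *probable*
outcomes; 1 + 2 positive answers on Q5a/Q5b alongside 3 *definite*
outcomes).  The constraints pin every edge except the outcome attached to a
negative Q2b/Q3b, where *unlikely* was chosen as the clinically conservative
reading (no dechallenge response observable and no irreversibility to
excuse it); either choice leaves all validated properties intact.

Response coding follows the tool: "Yes" is positive everywhere except Q3a,
where "Unassessable" (single-dose, intermittent or unstoppable therapy, so
no dechallenge can be observed) also counts as positive, and Q4a, where
"Low" is positive and "High"/"Unsure" are negative.  A written response is a
*binary* answer; an **unanswerable** question (no information) is a distinct
state that halts traversal ("stuck") and codes the assessment
*unassessable*.

## Study design

`allocate` assigns, per case, half the raters to each method.  For four
raters and two methods there are six rater-half × method combinations; cases
are processed in blocks of six within which each combination appears exactly
once, in random order, so per-pair case counts stay near-balanced (exactly 8
per pair at 48 cases).  With more raters the combination set grows
combinatorially and allocation falls back to an independent random half per
case.  `randomize_order` permutes each rater's case order independently and
uniformly.  All randomness is drawn from a named, seeded
`numpy.random.default_rng` (PCG64) recorded in the allocation, so designs
are reproducible from their seed.

## Agreement statistics

* **Proportions.**  Exact agreement is the diagonal mass of the 5×5 pooled
  cross-tabulation (an unassessable–unassessable pair agrees).  Extreme
  disagreement is ordinal distance ≥ 2 on the 1..4 ranks, plus the explicit
  one-sided rule for pairs with exactly one unassessable rating
  (unassessable has no rank).  Specific agreement per category k is
  2n₍kk₎ / (2n₍kk₎ + off-diagonal involvements of k); categories never used
  are reported undefined (NaN), not zero.
* **Pairwise Cohen κ** is delegated to
  `statsmodels.stats.inter_rater.cohens_kappa`; the linearly weighted
  version first removes every case with an unassessable rating and uses
  w₍ᵢⱼ₎ = 1 − |i−j|/3 on the 4×4 ordinal table.
* **Stuart–Maxwell** uses `statsmodels` `SquareTable.homogeneity`; unused
  categories are dropped first, and a still-singular covariance is reported
  as undefined rather than significant.  On two categories the statistic
  equals McNemar's (b−c)²/(b+c) exactly, which the tests verify.
* **Global κ for the incomplete design** (authored here): P₀ is the mean
  within-case pair weight with cases weighted equally; Pₑ treats raters as
  interchangeable.  Two Pₑ constructions are exposed because the literature
  admits both: `pe="pooled"` (default) squares the pooled marginal
  distribution of all ratings; `pe="per_rater"` averages products of
  per-rater marginals over co-rating rater pairs, weighted by cases shared.
  On the reference study's printed aggregates the pooled variant reproduces
  the published unweighted 0.61 (introspection arm) and linearly weighted
  0.73/0.45, while giving 0.25 against a published 0.27 for the unweighted
  flowchart arm — the published value evidently used per-rater information
  that the printed tables do not contain, which is precisely why both
  variants are implemented and compared.  Confidence intervals are
  estimate ± t₍n−1,0.975₎ × SE with the jackknife SE from leave-one-case-out
  pseudo-values (t rather than normal quantiles because n = 48 is small).
* **ICC(1,1)**: one-way random-effects ANOVA with categories coded
  definite = 1 .. unlikely = 4 (the ICC is invariant to affine recoding;
  the direction is documented, not material) after excluding cases with any
  unassessable rating; the interval is the exact F interval
  ((F/F₀.₉₇₅ − 1)/(F/F₀.₉₇₅ + k − 1), …), which reproduces the reference
  study's published intervals to both printed decimals and is cross-checked
  against `pingouin.intraclass_corr` in the tests.  When MSW = 0 the
  interval degenerates at 1.
* **Method comparisons.**  The difference in exact agreement uses the
  paired Wald interval on the discordant counts (the unpaired Wald variant
  is available behind `ci_method=`) and McNemar's chi-square without
  continuity correction (correction behind a flag).  Pairwise kappas are
  compared by a paired t test over the six rater pairs.
* **Sensitivity analysis** drops unassessable ratings, excludes cases left
  with fewer than two ratings per method, and reruns the full suite.
* **Reporting** rounds to two significant figures below 0.1 and two
  decimals otherwise, halves away from zero.

## Question-level diagnostics

Test selection for response cross-tabulations is fixed as: Pearson
chi-square without continuity correction when every expected count is at
least 5, otherwise the Fisher–Freeman–Halton exact test.  SciPy only
provides the 2×2 exact test, so the 2×c case is computed here by exhaustive
enumeration over the fixed margins (sum of conditional probabilities of
tables no more probable than the observed one); it was validated against R's
`fisher.test` on all printed question rows, and the chosen rule reproduces
the reference study's published p-value column exactly (including the
chi-square 0.008 on Q4a).  Whether that column used Yates' correction is
not stated; the correction is available via `yates=True`.  Group odds ratios
use Woolf logit intervals, with the 0.5 continuity correction applied and
flagged when a cell is zero.  Question-level and outcome-level agreement are
deliberately separate reports: raters can disagree on answers yet reach the
same outcome.

## Synthetic cohort

Each synthetic case carries a latent causality category and a per-question
true state, kept mutually consistent by sampling the facts along a flowchart
path whose outcome *is* the latent category (off-path facts come from
marginal rates and never influence an error-free traversal).  That shared
truth is what correlates the two methods' ratings, as the analysis assumes.
Defaults are the reference study's conditions: 48 cases, four raters (two
clinicians, two pharmacists), category mix (3, 29, 25, 32)/89 from the
pooled assessable flowchart outcomes, and an 8 % uninformative-case rate
(between the two arms' observed unassessable fractions, 13/96 and 7/96).
The introspective rater recovers the latent category with probability
1 − e (default e = 0.15, chosen so pooled exact agreement settles in the
observed 0.6–0.8 band) and otherwise moves to an adjacent category tilted by
a log-space category-bias vector (raters 2/3/4 lean toward probable/
possible/unlikely respectively, mirroring the study's observed rater
preferences).  Flowchart answers flip the true fact with probability e per
question, shifted on the log-odds scale by a profession effect on the two
subjective questions (default ± log(5.1)/2 on Q4a, matching the published
clinician-vs-pharmacist odds ratio; the Q4b shift favours pharmacists).
A `uniform_random` profile ignores the truth entirely and is used for null
calibration (mean global κ ≈ 0 over replicates).

What the generator does **not** emulate: clinical narratives, drug
pharmacology, inter-question correlation of errors within a rater, rater
learning over the assessment sequence, and the "unable to choose between
two categories" route to unassessable (only the stuck route is modelled).
Passing tests on synthetic data therefore demonstrate the statistical
machinery and the engine's contracts, not the behaviour of human raters.

## Reference fixtures and the reconstruction

The printed tables of the reference study ship as CSV fixtures.  A
record-level dataset is reconstructed from them for the end-to-end checks:
the outcome-pair multiset per method is exactly the printed
cross-tabulation, the rater pairs per case follow the printed per-pair case
counts (complementary across methods, as the design requires), and the deal
of outcome pairs to rater pairs — which the printed tables do not determine
— is a fixed seeded interleave, labelled synthetic.  Statistics that depend
only on pooled tables (agreement proportions, specific agreement,
pooled-marginal global κ, ICC) are invariant to that deal; per-pair
statistics on the reconstruction are indicative only.

## Problem sizes

The test suite and acceptance checks use the study's own scale (48 cases,
4 raters) throughout; the stochastic calibration checks use 60 replicate
studies for the exact-agreement band, 200 for the null-κ check, 1,000
response replicates for the odds-ratio recovery, and n = 600 for the
category-mix goodness of fit.  The full suite runs in well under a minute.

## Known limitations

* The packaged chart is a constraint-validated transcription, not a copy of
  the original figure; the two under-determined terminal edges are a
  documented choice.
* The per-rater Pₑ variant cannot be checked against the published
  flowchart-arm κ because the record-level rater marginals were never
  printed.
* The exact-agreement difference CI method in the reference study is
  unnamed; paired Wald is the default here and gives a slightly narrower
  interval than printed.
* Fisher–Freeman–Halton enumeration is implemented for 2×c tables (the only
  shape the diagnostics produce); wider tables would need a network
  algorithm.
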