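# Methods

## Problem setting

Two cohorts of free-text documents — here, radiology reports of patients
whose tumors either carry an activating mutation (MUTANT) or do not
(WILDTYPE) — are compared at the level of *term presence per report*. The
question is purely descriptive: which terms appear in a systematically
different fraction of reports in one cohort than the other, and how strongly
does the presence of a term shift the odds that a report came from one
cohort? Whole-report classification (assigning a new report to a cohort from
all of its words jointly) is deliberately out of scope.

## Model

Counting is document-frequency based: a term either occurs in a report's
distinct-term set or it does not; within-report multiplicity is ignored.
This makes the per-term statistic a comparison of two binomial proportions,
df_S/N_S vs df_H/N_H, and the Bayes posterior

    P(S|W) = P(W|S)·P(S) / (P(W|S)·P(S) + P(W|H)·P(H))

a monotone function of their ratio. The "naive" independence assumption
never actually enters at the single-term level — each term is scored in
isolation — which is exactly why the per-term posterior is well defined
without a joint document model.

### Likelihood smoothing

P(W|cohort) is estimated as (df + α)/(N + 2α), default α = 1. The formula is
the posterior mean of a Beta(α, α) prior on the inclusion probability; α > 0
is *required* when df ∈ {0, N} because the unsmoothed ratio makes the Bayes
denominator zero (term absent from both cohorts) or pins the posterior to
exactly 0/1, which misrepresents what one-sided absence in a finite sample
can support. Reported frequencies (`f_mut`, `f_wt` columns) stay unsmoothed
so they remain exact ratios of observable counts; smoothing affects only the
posterior columns.

### Priors

Default is empirical, P(S) = N_S/(N_S + N_H). The corpora this method
targets are near-balanced by design, so the empirical prior is close to 1/2;
a fixed-prior mode (default 0.5, the spam-filtering convention) is provided
for sensitivity analysis and for scoring tables whose cohort sizes reflect
collection artifacts rather than base rates.

### Percent difference

The field reports "percent difference" between cohort frequencies without a
standard definition. The package uses the symmetric mean-relative form
100·|a−b|/((a+b)/2), which is symmetric in its arguments, scale-free, and
bounded by 200; a max-relative variant (100·|a−b|/max(a,b), bounded by 100)
is switchable for sensitivity checks. The choice is isolated in one function
and does not influence posterior-based ranking.

## Text processing

* **Tokenization**: lowercase alphabetic runs; tokens containing digits are
  dropped entirely (measurements, dates, series labels), as are 1-character
  tokens. Sentence punctuation (. ; :) is kept as sentinel tokens because
  negation scopes must not cross it.
* **Stemming**: the Porter (1980) suffix-stripping algorithm, implemented
  in-package, with one extension: a terminal `-sis` is rewritten to `-ses`
  before step 1a. Plain Porter stems *metastasis* → `metastasi` but
  *metastases* → `metastas`, splitting one clinical concept across two table
  rows; the Greek-plural rule conflates such pairs (metastasis, stenosis,
  diagnosis, ...) without affecting the algorithm's published behavior on
  its classic test words (frozen in `tests/test_stemming.py`).
* **Negation**: a minimal NegEx-style proximity check. Cues (default: no,
  not, without, absent, "free of", "negative for") negate the following 3
  tokens; any sentence punctuation, adversative conjunction (but, however)
  or new cue resets the scope. A negated mention becomes a *separate term*
  rendered `[no] <surface>` — "no discrete mass" produces `[no] discrete`,
  which may legitimately co-occur with bare `discrete` in one report. No
  hedge/uncertainty detection, no section segmentation, unigrams only.
* **Display forms**: terms are keyed by (stem, negated); the display string
  uses the most frequent raw surface mapped to the stem (ties broken
  lexicographically), so a table row reads "[no] discrete" rather than
  "[no] discret".

## Predictor sets and the group test

Per cohort, terms with own-cohort posterior strictly > 0.5 are ranked by
|p_mut − p_wt| (= |2·p_mut − 1|, because posteriors are complementary) and
the top k kept (defaults k = 6 for MUTANT, 4 for WILDTYPE, matching the
typical size of reported descriptor groups; both configurable). A rare-term
floor (min_df = 5 total reports, configurable) suppresses one-off typos
before ranking.

Each set is evaluated by pairing, per term, the own-cohort posterior with
the other-cohort posterior and applying the Wilcoxon signed-rank test:
zeros dropped, midranks for ties, statistic min(W+, W−), exact p by
convolution over all 2^n sign assignments for n ≤ 25 (midranks are doubled
so the convolution runs on integers), normal approximation with tie
correction and 0.5 continuity correction beyond. Default alternative is
two-sided. **Caveat, by construction**: with complementary posteriors every
pair difference in a well-formed set has the same sign, so the exact p is a
deterministic function of the set size (one-sided (1/2)^n). The test
therefore certifies the selection construction rather than adding
independent evidence, and the group means are the substantive output; the
test is included because it is the field's reporting convention. No
multiple-testing correction is applied across the two groups.

## Synthetic corpus generator

The generator emulates only the statistical assumptions the analysis rests
on, not clinical language:

* each report includes each **marker** word independently with its cohort's
  inclusion probability (Bernoulli per report — presence/absence is all the
  pipeline sees);
* markers flagged `negated_context` are embedded as a standalone "no
  <word>." sentence, so negation tagging is exercised and the marker is
  recoverable only as its `[no]` term;
* plain markers are embedded as a bare "<word>." sentence — marker
  sentences carry *no filler words*, because any filler would co-occur with
  the marker and acquire the same cohort differential, contaminating
  recovery checks;
* **background noise** words are pronounceable consonant–vowel nonsense
  strings ("badaga", ...) drawn uniformly from a fixed vocabulary; their
  construction makes them fixed points of the stemmer and guarantees zero
  collision with marker stems (collisions are detected and rejected);
  per-report counts are Poisson (default mean 20, minimum 1).

Defaults state the validation scenario used throughout: 2,000 reports per
cohort (the scale of a realistic single-institution pull), markers at
(q_mut, q_wt) = (0.30, 0.10), (0.25, 0.12) and negated (0.10, 0.30) —
report-frequency differentials of the size actually observed for imaging
descriptors — over 500 background words. For each marker the analytic
posterior q_mut·ρ/(q_mut·ρ + q_wt·(1−ρ)) is exact ground truth up to
smoothing (O(α/N) bias) and binomial sampling noise (± ~0.015 at N = 2000),
hence the ±0.03 recovery band used in the tests.

A green recovery test establishes that counting, smoothing, Bayes
arithmetic, negation handling and selection compose correctly under the
generator's independence assumptions. It does **not** establish robustness
to real-report phenomena the generator omits: correlated descriptors,
section structure, hedged findings, template boilerplate shared across
cohorts, or per-patient report clustering (all reports are independent; in
real corpora one patient contributes many correlated reports and a
per-patient sensitivity analysis is advisable).

## Numerical and degenerate-input choices

* Posterior arithmetic is plain double precision; all inputs to Bayes' rule
  are strictly inside (0,1) by construction, so no log-space guard is needed.
* `percent_difference(0, 0)` and `analytic_posterior(0, 0, ·)` are hard
  errors, not NaN — a term in a table always occurs somewhere, so these
  signal caller bugs.
* Exact signed-rank p-values are dyadic rationals computed by integer-shift
  convolution; equality tests against enumeration hold to 1e−12.
* Ranking ties break by higher total document frequency, then lexicographic
  stem, making all orderings total and runs reproducible.
* Determinism: one numpy PCG64 stream seeded from the config seed; JSON
  artifacts are written with sorted keys and no timestamps, so identical
  config + seed reproduce byte-identical outputs.

## Known limitations

* The negation tagger is a fixed-window heuristic: it misses post-position
  negation ("mass is absent" negates nothing to its right) and long scopes,
  and double negation is not modeled.
* The stemmer is rule-based and English-specific; over-stemming can merge
  distinct concepts (e.g. *discrete*/*discretion* share a stem) — the
  display surface makes such merges visible in output tables.
* Exclusion filtering is substring-based; it stands in for institutional
  report-relevance screens whose precise rules are never published.
* Document frequency treats reports, not patients, as the sampling unit;
  posterior estimates are optimistic when one patient contributes many
  near-duplicate reports.
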