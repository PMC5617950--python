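# reportminer

Cohort-predictive term mining from free-text clinical reports.

Radiology reports describe tumor burden in words — "innumerable hepatic
lesions", "no discrete mass" — and those words are written with different
frequency for patients whose tumors carry different genotypes (e.g. KRAS-mutant
vs wild-type colorectal cancer). `reportminer` takes two labelled cohorts of
free-text reports and extracts the terms whose presence best separates them:

1. **Ingest & filter** — load a manifest (`report_id`, `patient_id`, `cohort`)
   plus one text file per report; drop administrative documents (billing,
   scheduling) by configurable substring rules.
2. **Text processing** — tokenize, stem (Porter suffix-stripping with a Greek
   plural rule so *metastasis*/*metastases* conflate), and tag negated mentions
   with a proximity window after cues like "no"/"without", so "no discrete
   mass" yields the term `[no] discrete`, distinct from bare `discrete`.
3. **Count** — per-cohort *document frequency*: the number of reports in each
   cohort whose distinct-term set contains the term. For term W and cohorts
   S (MUTANT) and H (WILDTYPE), the frequencies f(W|S) = df_S/N_S and
   f(W|H) = df_H/N_H.
4. **Score** — the per-term naive Bayes posterior

   P(S|W) = P(W|S)·P(S) / (P(W|S)·P(S) + P(W|H)·P(H)),

   with add-α smoothed likelihoods P(W|·) = (df + α)/(N + 2α) (default α = 1)
   and empirical or fixed cohort priors. P(H|W) = 1 − P(S|W).
5. **Select & test** — per cohort, the top-k terms with posterior strictly
   above 0.5, ranked by |P(S|W) − P(H|W)|; each predictor group is summarized
   by its mean posteriors and a Wilcoxon signed-rank test (exact sign-
   enumeration null for n ≤ 25, normal approximation with tie and continuity
   corrections beyond).

Because real institutional report corpora cannot be redistributed, the package
ships a synthetic-corpus generator that plants marker terms with known
per-cohort inclusion probabilities; the analytic posterior of each marker,
q_mut·ρ / (q_mut·ρ + q_wt·(1−ρ)) with ρ the MUTANT report share, gives ground
truth for end-to-end validation. See `docs/methods.md` for assumptions and
limitations.

## Worked example

```python
from reportminer import (
    MarkerSpec, SyntheticSpec, generate_corpus, process_report,
    build_term_table, score_all_terms, select_predictors, evaluate_predictor_group,
)

spec = SyntheticSpec(
    n_mut=2000, n_wt=2000,
    markers=(
        MarkerSpec("innumerable", q_mut=0.30, q_wt=0.10),
        MarkerSpec("confluent", q_mut=0.25, q_wt=0.12),
        MarkerSpec("discrete", q_mut=0.10, q_wt=0.30, negated_context=True),
    ),
    seed=7,
)
corpus, truth = generate_corpus(spec)
table = build_term_table((r.cohort, process_report(r.text)) for r in corpus)
scores = score_all_terms(table)

by_key = {(s.stem, s.negated): s for s in scores}
for marker in spec.markers:
    s = by_key[marker.term_key]
    print(f"{s.display:15s} f_mut={s.f_mut:.3f} f_wt={s.f_wt:.3f} "
          f"pct_diff={s.pct_diff:5.1f} p_mut={s.p_mut:.3f} "
          f"(analytic {truth.posteriors[marker.term_key]:.3f})")

set_mut, set_wt = select_predictors(scores, k_mut=2, k_wt=1)
ev = evaluate_predictor_group(set_mut, alternative="greater")
print("MUTANT predictors:", [t.display for t in set_mut.terms])
print(f"group means: own={ev.mean_own:.3f} other={ev.mean_other:.3f} "
      f"p={ev.result.p_value:.3g} ({ev.result.method})")
```

prints

```
innumerable     f_mut=0.292 f_wt=0.103 pct_diff= 95.7 p_mut=0.739 (analytic 0.750)
confluent       f_mut=0.261 f_wt=0.121 pct_diff= 72.8 p_mut=0.681 (analytic 0.676)
[no] discrete   f_mut=0.097 f_wt=0.309 pct_diff=104.9 p_mut=0.238 (analytic 0.250)
MUTANT predictors: ['innumerable', 'confluent']
group means: own=0.710 other=0.290 p=0.25 (exact)
```

Reading it: `innumerable` was planted in 30% of MUTANT and 10% of WILDTYPE
reports; its observed report frequencies (0.292 / 0.103) recover that, the
symmetric percent difference between the cohort frequencies is ≈96%, and the
estimated posterior P(MUTANT | term present) = 0.739 sits within sampling
error of the analytic 0.750. The negated marker is recovered as the composite
term `[no] discrete` and points the other way (p_mut = 0.238, i.e. a
wild-type predictor). The signed-rank p for a 2-term group is floored at
(1/2)² = 0.25 — with complementary posteriors the test certifies the
construction and scales only with group size, which is why it is reported
alongside, not instead of, the group means.

## Command line

```
reportminer demo     --seed 5 --out out/         # simulate + analyze + recovery report
reportminer simulate --config run.yaml --out corpus/
reportminer ingest   --config run.yaml           # load + filter, write filtered manifest
reportminer analyze  --config run.yaml           # full pipeline on a real corpus
reportminer evaluate --config run.yaml           # re-run selection + group test
```

`analyze` writes `term_table.csv`, `term_scores.csv`, `predictor_sets.json`,
`group_evaluation.json` and `run_summary.json` to the output directory; all
outputs are deterministic given the config and seed.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` generates the default
synthetic corpus with the given seed, runs the complete pipeline (filter →
process → count → score → select → evaluate), prints the recovered predictor
sets, the maximum absolute error of the estimated marker posteriors against
their analytic values, and the group evaluations, and writes the JSON target
map to `--out`.
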