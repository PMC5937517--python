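# adrminer

Association-rule mining between pharmacotherapy and laboratory-derived
adverse events, for pharmacoepidemiologists screening hospital EHR extracts
for safety signals — including *negative* (protective) associations that
plain support/confidence mining cannot distinguish.

## The method

Patients are transactions; a patient's items are the active-ingredient drug
codes they were exposed to and the adverse-event (AE) terms graded from
their abnormal laboratory results. Mining proceeds in two steps:

1. **Frequent drug itemsets** (classic level-wise Apriori with join + prune)
   at minimum support `min_sup` (default 165 patients, i.e. 1% of a
   16,527-patient cohort; a fraction is also accepted).
2. **Chi-square screening.** For each frequent drug combination X and AE
   term Y, the 2×2 table (a, b, c, d; n = a+b+c+d) gives the Pearson
   statistic

   χ² = n(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)],  df = 1

   and the signed screening statistic

   **comp** = sign(ad − bc) · √χ²  = √n · φ   (φ = phi coefficient).

   A rule is kept when its confidence a/(a+b) ≥ `min_cof` (default 10%) and
   |comp| exceeds the minimum test value `min_tev` derived from the χ²(1)
   critical value at level α (3.841 at α = 0.05 in the default `paper`
   mode; its square root 1.960 in `sqrt_scale` mode). comp > min_tev flags
   a positive association, comp < −min_tev a negative one, and |comp| ranks
   rule strength.

A conventional support/confidence miner is included as the baseline, and
`compare` reports both rule sets per stratum (antecedent size × direction)
with Wilcoxon–Mann–Whitney rank-sum p-values. A configurable grading engine
maps laboratory values to CTCAE-style severity grades 1–4, and a synthetic
cohort generator plants known odds ratios so every stage is testable without
patient data.

## Worked example

```bash
adrminer simulate --seed 42 --out demo
adrminer mine --exposures demo/exposures.csv --adverse-events demo/adverse_events.csv \
              --min-sup 0.01 --min-cof 5 --out demo/rules.tsv
adrminer evaluate --rules demo/rules.tsv --truth demo/truth.json
```

The demo cohort has 5,000 patients, 10 drugs and 6 AEs, with two planted
effects: OR(drug00, ae00) = 3 and OR(drug01, ae01) = 1/3. The miner prints

```
modified miner: 14 rules over 4855 patients -> demo/rules.tsv
```

and the two strongest rules in `demo/rules.tsv` are

```
antecedent  consequent  a    b    c    d     n     support  confidence  comp     direction
drug00      ae00        436  556  754  3109  4855  0.204    43.95       +15.96   positive
drug01      ae01        77   879  741  3158  4855  0.197    8.05        -8.11    negative
```

drug00 raises ae00's frequency from 19.5% (unexposed) to 44.0% of exposed
patients (comp ≫ 3.841: positive rule), while drug01 lowers ae01 from 19.0%
to 8.1% (comp ≪ −3.841: negative rule). `evaluate` scores the mined rules
against the generator's truth:

```json
{"n_rules": 14, "n_truth": 2, "recall": 1.0,
 "precision": 0.143, "sign_accuracy": 1.0}
```

Both planted pairs are recovered with the correct sign; the remaining rules
are correlates induced by co-prescription and overlapping exposures — the
reason the screen reports association, never causation. `adrminer compare`
on the same cohort retains 329 conventional rules vs 14 screened ones.

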