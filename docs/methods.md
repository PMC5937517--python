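# Methods

## Model and procedure

The miner treats a hospital admission cohort as a transaction database:
patient *i* carries a set of drug exposures (active-ingredient codes,
deduplicated — repeat prescriptions contribute once) and a set of
adverse-event terms (an AE is "present" at any grade ≥ 1; grade-stratified
mining is deliberately not the default, since the screen targets event
occurrence).

**Step 1 — frequent itemsets.** Level-wise Apriori with the classic
join/prune candidate generation: frequent (k−1)-itemsets sorted
lexicographically are joined on their first k−2 items, and any candidate
with an infrequent (k−1)-subset is pruned before support counting
(anti-monotonicity). Support is an absolute patient count; a fractional
`min_sup` is converted by flooring (1% of 16,527 → 165, the default).
`max_antecedent` defaults to 2 because single-drug and two-drug antecedents
are the clinically reported granularity; it is configurable upward.

**Step 2 — signed chi-square screen.** For each (frequent itemset X, AE
term Y) the 2×2 table is counted over the full cohort: a = exposed with the
event, b = exposed without, c = unexposed with, d = neither. The screen
uses

    chi2 = n(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)]          (df = 1)
    comp = sign(ad − bc) · sqrt(chi2) = sqrt(n) · phi

and retains rules with confidence 100·a/(a+b) ≥ `min_cof` and |comp| >
`min_tev(alpha, mode)`. The sign of comp equals the sign of ad − bc, hence
agrees with the odds ratio's side of 1: positive rules raise the event
frequency, negative rules lower it. |comp| ranks rule strength.

### The two threshold modes

`min_tev` is derived from the χ²(1) upper-α critical value, 3.841 at
α = 0.05. Because comp is on the *root* scale (it is asymptotically
standard normal under independence), two defensible screens exist:

* `paper` (default): compare comp directly against 3.841. This is the
  literal published procedure and is deliberately conservative — it
  corresponds to a two-sided normal test at roughly α ≈ 1.2×10⁻⁴.
* `sqrt_scale`: compare against √3.841 = 1.960, the statistically
  consistent threshold whose two-sided flag rate under the null is α.

Both are shipped because the published account mixes the two scales; the
null-calibration simulation in the test suite verifies that `sqrt_scale`
attains its nominal size and that `paper` flags strictly less often.

### Reading of the screening-statistic definition

comp is implemented as the signed square root of χ². This reading is fixed
by reconstruction: rebuilding the cisplatin→anemia table from its published
marginals (support 0.174, confidence 61.426%, event total 6,426, n 16,527)
gives χ² ≈ 745.6, whose signed root 27.31 matches the published comp 26.897
within 1.5%, while a signed χ² itself (≈ +746) is irreconcilable. The same
holds for cisplatin→neutrophil count decreased (46.98 vs 46.431, 1.2%).
The residual percent-level disagreement is exactly the rounding carried by
the three-decimal printed support, which moves the reconstructed margin
a+b by up to ±0.5/0.001 ≈ a few patients per thousand.

### Rule support definition

A rule's reported `support` is the *antecedent* itemset's support fraction,
not the joint a/n: across published single-drug cisplatin rules the support
is nearly constant (0.168–0.174) over seven different AEs, which fits the
antecedent reading (joint support would covary with each rule's
confidence). `support_def="joint"` switches to a/n.

### Validity and multiplicity

The χ² applicability condition — n > 40 and all four expected counts ≥ 5 —
is computed per rule and attached as a `valid` flag; invalid rules are
emitted flagged, never silently dropped. No multiple-testing correction is
applied by default (matching the published procedure); `bh_correct=True`
additionally requires a Benjamini–Hochberg adjusted two-sided p ≤ α across
all candidate pairs, for responsible use at scale.

### Denominator choice

Every AE uses the full cohort n as its 2×2 denominator: patients never
tested for an analyte are counted as event-free. The alternative
(per-test denominators) cannot be distinguished from the published
marginals at better than ~1.5% residual; the full-cohort convention
reconstructs them more closely and keeps all rules on one denominator.

## Grading engine

Laboratory values map to severity grades 1–4 via per-(AE, test) rules: an
ordered boundary list in the rule's severity direction (`below` or
`above`), expressed in native units (`absolute`), as multiples of the
relevant reference limit (`ratio`), or as signed offsets from it
(`offset`). Conventions fixed here: values inside the reported reference
interval are grade 0; a value exactly on a boundary takes the more severe
grade; a patient's grade for a term is the worst over all measurements
(idempotent rollup). Relative rules applied to rows missing their
reference limit grade as 0 and are tallied as ungradeable. The shipped
`data/example_grading.yaml` is an illustrative CTCAE-like table for eight
laboratory AEs, not the official criteria. Incidence percentages are
rounded half-up to two decimals, matching clinical-table convention.

## Record validation

Only case deletion is implemented: rows with missing identifiers,
non-numeric laboratory values, or inverted reference intervals
(ref_low ≥ ref_high) are dropped and tallied per rule in an exclusion
report. Estimation, variable deletion and pairwise deletion are rejected
with a configuration error because they require dataset-specific manual
review. The patient universe of the transaction database is the union of
ids across the exposure and AE tables; a patient appearing in neither
table has no representation in CSV input and therefore cannot contribute
to n (the synthetic generator's `Cohort.itemset_db()` restores such
patients from its truth record).

## Synthetic cohort generator

The generator emulates the *shape* of an oncology EHR extract, not its
content: per-drug independent Bernoulli exposures (optionally with pairwise
co-prescription boosts — among patients on drug i, drug j is redrawn at
min(1, prevalence_j × boost) — sufficient to create two-drug antecedents);
AE occurrence from a logistic model, logit p = logit(baseline) +
Σ_exposed log OR(drug, AE), so effects compose additively on the log-odds
scale; severity grades drawn from a per-AE distribution (default
0.60/0.25/0.10/0.05 over grades 1–4, the mild-dominated shape of routine
laboratory AE tables). Everything is reproducible from a single seed.

What it does **not** emulate: longitudinal dosing and drug–event timing,
correlated laboratory panels, confounding by indication, informative
testing (who gets measured), or realistic lab-value trajectories — grades
are drawn, not derived from values. Passing recovery tests on these
cohorts therefore demonstrates the *screen's* operating characteristics
(size and power against planted marginal odds ratios), not robustness to
confounding, which no association screen provides.

### Simulation study conditions

* Null calibration: 200 cohorts of n = 2,000 patients, 20 drugs at
  prevalence 0.2, 10 AEs at baseline 0.2, all odds ratios 1. The flag rate
  of the `sqrt_scale` screen over all (frequent itemset, AE) pairs is
  checked against α = 0.05 within two standard errors of the replicate
  mean; the flag rate is measured with a vanishing confidence floor so the
  comp screen is the only filter.
* Recovery: 50 cohorts of n = 5,000 with one planted OR = 3 and one
  OR = 1/3 pair (exposure and baseline rates 0.2). The confidence floor is
  set to 5% in this experiment by arithmetic necessity: a protective
  OR = 1/3 on a 20% baseline yields a conditional event rate of ~7.7%, so
  the cohort-level default of 10% would censor every planted negative rule
  regardless of its statistical strength. Mean recall ≥ 0.9 and 100% sign
  agreement are required at the conservative `paper` threshold.

These problem sizes run the full acceptance suite in well under a minute
per criterion on a single core.

## Numerical choices

* χ² uses the determinant shortcut; the test suite verifies equivalence to
  the expected-count form Σ(O−E)²/E at 1e-9 relative tolerance, and
  comp² = χ² at the same tolerance.
* Zero-margin tables raise `UndefinedStatisticError` from the statistics
  functions; inside the miners such pairs carry NaN statistics — the
  modified miner cannot retain them, the conventional miner keeps them
  with direction `none`.
* Ordering is deterministic everywhere: itemsets lexicographic, rules by
  |comp| descending with lexicographic tie-breaks (NaN comp last).
* The rank-sum comparison uses exact enumeration when the pooled sample
  has ≤ 12 tie-free observations, otherwise the normal approximation with
  tie and continuity corrections (via scipy). Which variant produced the
  published stratum p-values is unknowable; this default is documented
  rather than asserted.
* Wall-clock runtimes in the comparison report are informational only.

## Known limitations

Rules express correlation only — no temporal sequencing (drug before
event), no confounding adjustment, no causal claim. Exact published rule
counts from the private hospital cohort are not reproducible and are out
of scope; the implementation instead guarantees the structural properties
that comparison rests on (the screened rule set is always a subset of the
conventional one, and shrinks monotonically in min_cof and min_tev).
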