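# Methods

## Problem and data model

Spontaneous reporting systems collect individual case safety reports: one
record per suspected adverse-event episode, naming one or more suspected
drugs, one or more adverse-event preferred terms (PTs), and reporting
covariates (sex, age band, seriousness, report type, reporter occupation,
reporting institution).  Signal detection asks, for each (study drug,
event) pair, whether the event is reported disproportionately often with
the drug relative to a set of comparator drugs.

`pvmlsd` works at the report level with a simple documented table dialect:
TSV files with a fixed header, multi-valued drug/event cells joined by
`;`.  Covariate enums admit an explicit `unknown` member (except report
type, whose three categories are exhaustive); `unknown` is its own bucket
and is excluded from the eighteen named covariate features.  No
case-versioning or duplicate-report resolution is attempted — each row is
taken as one independent report.

## Gold-standard labeling

Reference labels from multiple regulatory authorities are merged by union
into one set of (drug, PT) pairs; matching is exact at PT level with no
hierarchical roll-up.  The three-way rule: a pair is *label-positive* if
on the study drug's own label; *label-negative* if absent from the labels
of the study drug **and** of every therapeutic class-mate (same first five
ATC characters and mechanism tag); otherwise *unknown*.  Union-merging
maximizes label-positive sensitivity; exact matching keeps the rule
reproducible.  Summary percentages are round-half-up integers, matching
the usual presentation of such tables.

## Feature construction

One row per distinct event observed with the study drug, 23 features:

* `a, b, c, d` — the 2×2 report counts.  A report with k event terms
  contributes to k pairs' `a` cells but once per cell; a report naming
  both the study drug and a comparator counts toward the study-drug row
  (exposure of interest dominates); reports naming neither set are
  ignored.
* 18 covariate counts — sex 2 + age 3 + serious 2 + report type 3 +
  occupation 5 + institution 3, tallied over the reports in cell `a`
  (these features describe the specific event, not the drug's whole
  reporting profile).  This is the only decomposition of the named
  covariate families consistent with "22 numeric features".
* the event's system organ class (SOC), stored as one categorical and
  one-hot expanded over the dictionary's closed SOC list only at encoding
  time, so train/test/unknown matrices always share a schema.

## Disproportionality statistics

*Crude ROR*: `(a·d)/(b·c)` with Wald 95% interval
`exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`; when any cell is zero the
Haldane–Anscombe 0.5 correction is applied to all four cells and flagged.
*Adjusted ROR*: case/non-case logistic regression at report level (outcome
= report contains the event; exposure = study drug; covariate families
one-hot against their first level; never-observed levels are dropped to
keep the information matrix nonsingular).  The default covariate set
excludes SOC, because the outcome event fixes its own SOC (structural
collinearity); per-report SOC-presence indicators can be added explicitly.
Complete separation or a constant outcome raises a typed error; the
pipeline falls back to the crude ROR for such pairs.  The intervals are
frequentist Wald intervals throughout.

*IC*: the shrinkage observed-to-expected form,
`IC = log2((a+0.5)/(E+0.5))` with `E=(a+b)(a+c)/N`, with exact
gamma-posterior credible bounds (`Gamma(a+0.5, rate E+0.5)`, quantiles at
2.5%/97.5% on the log2 scale).  This form is deterministic and
oracle-checkable; the classical closed-form approximation
`IC − 3.3(a+0.5)^−½ − 2.0(a+0.5)^−³ᐟ²` is kept as an independent
cross-check only (they agree within 0.05 bits for a ≥ 5).

Signal criteria: ROR lower bound ≥ 1 (inclusive); IC025 > 0 (strict).

## Classification protocol

SMOTE balances the gold standard to exact class equality: each synthetic
minority point is `x_i + u·(x_j − x_i)`, `u ~ U(0,1)`, with `x_j` among
the k = 5 nearest minority neighbors (Euclidean distance on the encoded
matrix, one-hot SOC columns included; SMOTE-NC was considered and rejected
for simplicity).  By default SMOTE runs **after** the stratified 75/25
split, on the training portion only, to keep synthetic neighbors from
leaking across the split; `smote_before_split=True` reproduces the
balance-then-split ordering some studies describe.

The gradient-boosted classifier uses xgboost with the published settings
(eta 0.01, 100 rounds, depth 4 or 6, min_child_weight 1, colsample 0.4 or
0.7, gamma 0, seed 200); the random forest uses 500 trees with √p features
per split, since no published settings exist for it.  Stratified
five-fold tuning over a small grid (depth {3,4,5,6} × colsample
{0.4,0.7,1.0}) is available but off by default — the defaults are used
verbatim, which keeps runs fast and exactly reproducible; score ties in
the grid resolve to the first candidate in declared order.

Evaluation is deliberately asymmetric, mirroring the protocol this
framework follows: tree ensembles are scored by ROC AUC on the held-out
25%, while the disproportionality methods are scored on the **entire**
gold standard, using their signal-defining statistic (ROR lower bound,
IC025) as the ranking score; `dpa_on_test=True` gives the symmetric
variant.  The operating threshold scans t = 0.00 … 1.00 in steps of 0.01
and maximizes the single-point ROC area, i.e. balanced accuracy — the
natural reading of "best AUC at a threshold", since a single operating
point has ROC area (sensitivity+specificity)/2.  Ties go to the highest
threshold.  The decision rule is inclusive (`score ≥ t`) everywhere,
consistent with the inclusive ROR criterion.  PPV/NPV are reported as
missing when their denominator is zero.

## Synthetic data generator

The generator emulates the structure of a national SRS extract for one
study-drug family: each report draws **one** exposure drug from marginal
exposure probabilities, covariates independently from realistic category
distributions, and each event term independently with probability
`baseline × rate_ratio(drug, term)` capped at 0.95; zero-event reports
are redrawn.  Defaults (chosen once as the study conditions): 20,000
reports; 90 terms over 10 SOCs with baselines cycling
{0.005, 0.01, 0.02, 0.04}; one study drug (exposure 0.25), six comparators
(0.10 each), two class-mates (0.075 each); 30 pairs planted on the study
drug at rate ratio 5; `label_noise` 0.2 — the seeded 20% of planted pairs
held out of the study drug's label and placed on a class-mate's label so
they fall in the unknown partition as recoverable true signals.  A
handful of null terms also lands on class-mate labels so that all three
label statuses occur.

Known simplifications: event terms are conditionally independent given
the drug (no syndrome co-occurrence), covariates are independent of both
exposure and outcome by default (so crude and adjusted ROR coincide up to
noise; a confounded variant can be built by passing shifted covariate
distributions per drug scenario manually), one drug per report, no
reporting-delay dynamics or duplicates.  Passing tests on this generator
therefore demonstrates correctness of the counting, statistics and
protocol — not performance on real reporting data, where labels are
noisier, exposure is multi-drug and confounding is real.

## Numerical and reproducibility choices

All randomness (simulation, splitting, SMOTE, model seeds) derives from
integer seeds; a fixed configuration reproduces reports, splits, selected
hyperparameters and predictions bit-for-bit (xgboost runs single-thread).
Degenerate inputs raise typed errors rather than NaNs: empty report sets,
N = 0 tables, single-class label vectors, minority class ≤ k for SMOTE,
classes below 4 rows for splitting.  Test and acceptance problem sizes
(20,000-report simulations, 10-seed recovery loops, 10⁶-draw Monte-Carlo
quantile checks) were chosen so the full suite completes in well under a
minute on one CPU while keeping sampling noise far below the asserted
tolerances.

## Limitations

The framework's apparent performance depends strongly on how separable
the gold standard is; on the default synthetic scenario all four methods
score near-perfect AUC because planted effects are large and labels are
clean, which exercises the machinery but does not rank the methods the
way noisy real data would.  Label matching is exact at PT level; real
label extraction requires terminology mapping this package does not
attempt.  No multiple-comparison correction is applied to the
disproportionality criteria, matching standard practice for these
statistics.
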