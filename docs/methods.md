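# Methods

## Problem and analysis model

The package analyses cohorts of patients with grade 1–2 neuroendocrine
tumors of the small intestine (siNET) or pancreas (pNET) whose disease
course over three years from diagnosis is classified as stable (SD) or
progressive (PD, deaths folded in).  Each patient carries clinical
variables at diagnosis (gender, age, Ki-67 proliferation index, NET grade,
nodal/distant/liver metastasis, metastasis count, carcinoid-syndrome
symptoms), chromogranin A (CgA) as a multiple of the upper limit of normal
(ULN), 5-HIAA as a percent of its ULN, and 92 plasma proteins on a relative
log-abundance (NPX-like) scale.  A separate outcome-free control cohort
provides the reference distribution for the proteins.

The core method is association rule mining: every patient is encoded as a
*transaction* — the set of categorical items they carry — and the Apriori
algorithm enumerates all rules X → Y with

- support = number of transactions containing X ∪ Y (absolute count),
- confidence = count(X ∪ Y) / count(X),
- lift = confidence / (count(Y) / N),

where Y is restricted to an outcome item (SD or PD) or, in the
characterization pass, a fixed composite itemset such as
{female, CgA > 4 ULN}.  Rules with the same antecedent/consequent attribute
sets in a different order are redundant and removed; survivors are ranked
by lift, then support, then a lexicographic tie-break so output is fully
deterministic.

## Variable categorization

Continuous proteins are discretized against the 95% confidence interval of
the **control-cohort mean**: value < mean − z·SD/√n yields a "VAR < low"
item, value > mean + z·SD/√n a "VAR > high" item, and values inside the
interval yield no item (absence coding).  Notes on the choices:

- **z rather than t quantile.** At n = 143 the difference is below 0.002 on
  the CPE scale, and the z bound reproduces the printed control CPE lower
  bound 3.03 and control log-CgA interval [1.21, 1.37] exactly at two
  decimals.
- **Absence coding.** Values in the normal range contribute no item; every
  reported biomarker rule uses a "<" or ">" item, and emitting explicit
  "normal" items would inflate the item universe.
- **Strict inequalities, unrounded bounds.** Comparisons use the full-
  precision bounds; item labels round to 2 decimals.  A value exactly on a
  bound yields no item.
- Because the CI of the *mean* is narrow (half-width ≈ 0.16·SD at n = 143),
  roughly half of patient values fall below and half above the control
  interval for a null protein; each patient therefore carries ≈ 90 items.
  This matches the regime in which three-item antecedents reach supports in
  the low twenties out of 115 by chance only rarely, so mining at the study
  thresholds is tractable and selective.

Fixed clinical thresholds: CgA > 4 ULN (multiples configurable), 5-HIAA >
455 (%ULN), Ki-67 > 5% vs ≤ 5%, "> 10 metastases".  Gender, NET grade,
N/M status, liver metastasis and per-symptom items pass through as
categories, with "no CS symptoms" for an empty symptom set.  Age is not
discretized by default (no age item appears in any reported rule).
Treatment is kept on the patient record for the supporting statistics but
is not encoded as an item: treatments started after diagnosis, while the
rules use variables at diagnosis.

## Miner implementation

Counting uses one Python-integer bitmask of transactions per item; an
itemset's support is the popcount of the AND of its members' masks, so all
metrics are exact rational numbers.  Candidates of size k are generated by
joining frequent (k−1)-sets sharing a (k−2)-prefix with pruning of any
candidate having an infrequent subset.  Support is stored and thresholded
as an absolute count (the reported filters — "support > 20" — are counts).
The default search is 3 antecedent items + 1 consequent (max itemset size
4).  For a composite consequent the miner runs on the conditional database
of target-positive transactions (X is frequent there iff count(X ∪ Y)
clears the threshold), then computes confidence and lift against the full
database; this is exact and avoids enumerating size-5 itemsets globally.

The miner is verified against a brute-force enumeration oracle (all subsets
of the catalog, counted by scanning) on 200 random databases; itemsets,
counts and rule metrics agree to 1e-12.

### Filter profiles

| profile | support | lift | confidence |
|---|---|---|---|
| sinet_pd | > 20 | ≥ 1.2 | ≥ 0.70 |
| sinet_sd | > 14 | ≥ 1.2 | ≥ 0.70 |
| pnet_pd | > 14 | ≥ 1.25 | ≥ 0.70 |
| characterization | ≥ 8 | — | ≥ 0.80 |

Operators follow the printed symbols (strict for support, inclusive for
lift/confidence) and are configurable.  The characterization profile does
not filter on lift: with a 23/115 composite-target base rate, any rule at
confidence ≥ 0.94 necessarily has lift ≥ 4.69, so the "very high lift"
of that rule set is a property of the subgroup, not a selection criterion.
A minimum support of "30% of patients" is also quoted for the first-pass
mining; the selected-rule thresholds above are what the reported rule
counts use, so the profiles follow those, and the 30% floor remains
available through configuration.

### Known lift discrepancy

With 65/115 progressive patients, a confidence-1.00 PD rule has lift
115/65 ≈ 1.77 under the standard definition, whereas the source tables
print 2.08 (implying a ≈ 48% baseline).  The transaction base behind the
printed value cannot be reconstructed; this package implements the
standard definition and makes no attempt to match 2.08 (similarly for the
SD-rule lift 2.53 vs the implied 2.33).

## Rule-as-classifier diagnostics

A rule antecedent defines a binary test inside an optional stratum
(e.g. antecedent {CgA > 4 ULN} within females): the 2×2 table against the
outcome yields PPV, NPV, sensitivity and specificity.  Zero-denominator
proportions are reported as undefined rather than zero.  Report
percentages round half away from zero (62.5 → 63), matching clinical
reporting.

## Synthetic cohort generator

The generator emulates the study's data structure so the full pipeline is
testable without the (undeposited) original cohort:

- **Sizes and outcome mix**: siNET n = 115 with 65 PD / 50 SD, pNET n = 30
  with 22 PD / 8 SD, controls n = 143.  The realized PD count is exactly
  round(n · pd_fraction) before planted-rule overrides.
- **Clinical frequencies** per outcome group follow the published
  category counts (gender, N/M status, grade, treatment mix).  Grade
  missingness defaults to 0 (the analysis set was complete-case) and is
  configurable.  Ki-67 is drawn uniformly within the grade-consistent
  range (G1 < 3%, G2 3–20%).
- **CgA** is simulated as a log-normal per group using the published
  log-scale group means/SDs (control 1.29 (0.48), siNET PD 3.57 (1.37),
  SD 2.35 (1.01)) and exponentiated; the ULN is fixed at 1.0 internal
  unit so "CgA > 4 ULN" means raw value > 4.  **CPE** uses the published
  group summaries (control 3.09 (0.34), PD 3.32 (0.74), SD 2.96 (0.33)).
- **Other proteins** are normal on the NPX-like scale.  No distributional
  form is published for them, so normality is an assumption.  Proteins
  with a reported direction of association carry a fixed shift of
  0.3–0.55 control-SDs in the corresponding group; the rest are null.
  Control-level means/SDs for unnamed proteins are fixed package
  constants drawn once from plausible NPX ranges (2–10, SD 0.25–1.0).
  Proteins are independent by default (the analysis consumes only
  marginal cut-offs); an equicorrelation option exists for stress tests.
- **5-HIAA** (log-normal, PD-shifted), metastasis counts (shifted Poisson
  conditional on M1), liver metastasis and symptom rates per group are
  package choices on clinically plausible ranges, since only some of
  these frequencies are published.

All randomness flows from a single integer seed through independent
numpy `default_rng` streams; the same seed yields bit-identical CSVs.

### Planted ground-truth rules

A `PlantedRule` makes `carrier_fraction` of the cohort antecedent-positive
(raw values are pushed safely past the relevant cut-offs), makes **all
remaining patients antecedent-negative** by relaxing one antecedent item
(continuous items preferred, so categorical frequencies are disturbed
minimally), and resamples carrier outcomes as Bernoulli(`penetrance`).
Forcing non-carriers negative is essential: the mined confidence of the
planted rule is then a binomial draw around the penetrance, giving a clean
recovery target (at the realistic CgA group means, background
antecedent-positive patients would otherwise dilute confidence well past
any binomial band).  Recovery holds at |mean mined confidence −
penetrance| within 3 binomial standard errors.

### What passing tests do and do not show

The generator reproduces the marginal structure the analysis consumes
(group frequencies, group-wise biomarker locations, outcome mix) but not
real between-protein correlation, assay batch effects, informative
missingness, or the adjudication noise of clinical progression calls.
Tests therefore validate the *machinery* — categorization, exact counting,
selection arithmetic, diagnostics — and the recovery of effects the
generator plants, not the biological validity of any specific rule.

## Supporting statistics

- **Group summaries**: mean, sample SD (n−1), z-based CI of the mean;
  display rounds to 2 decimals.
- **LS-means ANOVA**: additive fixed-effects model (outcome group +
  treatment) fit by OLS (statsmodels).  The LS mean of a group averages
  the model prediction with equal weight over treatment levels (classical
  definition; the weighting is not otherwise specified).  The group F test
  compares against the model without group — identical to the type-III
  test for an additive model.  Empty group×treatment cells are an error.
- **Treatment-vs-progression test**: binary logistic fit by Newton ML
  (statsmodels Logit, tol 1e-10), likelihood-ratio test against the
  intercept-only model.  Complete separation is flagged and the LRT
  p-value is still reported from the boundary fit.  On a 2×2 design the
  LRT equals the G-test of the contingency table (verified in tests);
  type-I error is 5% ± 2% over 1000 null simulations at cohort-like sizes.
- **ROC AUC**: Mann–Whitney rank statistic with half-credit for ties,
  oriented as higher score = more likely PD; AUC < 0.5 markers (e.g. a
  stability-associated protein) are reported as-is, not flipped.

The two differing p-values printed for the CPE contrast in the source
(0.003 and 0.03) cannot be adjudicated without the raw data; neither is a
target of any test here.

## Problem sizes

Default analyses run at the study sizes (115/30/143).  The planted-rule
recovery study uses 200 seeds at n = 2000 with encoding projected to the
planted items (the projection only restricts the item universe; mining is
unchanged).  Calibration studies use 1000 simulations (logistic type-I
error, LS-mean recovery) and 200 simulations for AUC summaries.  These
sizes put every Monte-Carlo estimate's standard error well inside the
asserted tolerance.

## Known limitations

- Exact reproduction of the study's data-dependent rule counts (2231, 216,
  54, 29) is impossible without the original cohort; the pipeline
  reproduces the regime (order of magnitude, thresholds, arithmetic) and
  the desk-scale worked examples instead.
- The supplementary categorization table is not available; all
  non-biomarker thresholds are taken from the printed item vocabulary and
  are configurable.
- Whether low-tail items exist for every protein (vs only some) is not
  documented; they are implemented uniformly.
- pNET SD rules are not produced by the analysis scripts (8 patients).
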