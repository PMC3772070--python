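# Methods

## The extraction model

The rule engine is a shallow parser: no syntactic analysis beyond sentence
segmentation and token distances. A mention is produced in three stages.

**Candidate detection.** Sentences are segmented on `.!?;` and newlines
(with a small abbreviation guard: "e.g.", "Dr.", ...). Tobacco-term
lexicon matches anchor candidates; matching is case-insensitive and
offsets are 0-based half-open character offsets into the original text. A
*generic* smoking term ("smokes", "smoker") is suppressed when a
non-tobacco substance term (cannabis, marijuana, crack, ...) sits within
`max_tokens` tokens and no *explicit tobacco object* ("cigarettes",
"tobacco", "roll-ups") sits at least as close: "smokes cannabis" yields
nothing, "smokes cigarettes and cannabis" yields one mention. Nearby
candidates collapse into a single mention, anchored on the tobacco object
when one is present, else the leftmost term — the annotation is therefore
mention-level, at most one per sentence cluster.

**Classification.** Cues scope a candidate when they lie in the same
sentence within `max_tokens` (default 5) tokens — the standard
precision-preserving scope for clinical negation. A negation cue yields
*never* (hyphenated negatives such as "non-smoker" count, at distance 0), a
past cue *past*, a current cue *current*. A current cue that is the
candidate token itself ("smokes") is discounted when a negation or past cue
also scopes: in "never smokes" the verb is what is negated. Third-party
attribution cues ("family", "wife") force abstention.

**Abstention.** With `abstain_on_conflict` (the default) a mention scoped
by more than one cue class, or by none, produces no annotation. Missed
mentions are recoverable from later documents for the same patient; wrong
ones are not. Setting `abstain_on_conflict=False` resolves conflicts by
the fixed precedence never > past > current (negation is the most reliable
clinical signal, past-tense the next); bare mentions still abstain. This
trades precision for recall and is the knob the evaluation harness
exercises.

All lexicons ship as editable defaults (`RuleSet`, YAML-round-trippable,
`--rules` on the CLI). The default word lists are a reconstruction of
common clinical phrasing, not a canonical inventory; any deployment
against real notes should expect to iterate them against a local gold
standard using the error report.

## Patient-level resolution

Records from both sources are pooled as (date, status, source) triples —
a text annotation is dated by its source document, not by its position —
records before the referral date are discarded, and the earliest record
wins. Tie-breaks, both configurable:

* same date, structured vs text: **structured wins** (a deliberate
  clinician-entered field is stronger evidence);
* same date within text, different statuses: **current > past > never**
  (affirmative mentions are the higher-precision signal).

Cohort filters: referral inside the window; age at referral strictly
greater than 15 years; and, when set, at least `min_care_months` *calendar*
months of care computed day-of-month-aware from referral to care-end
("twelve months" means calendar months, not 365 days). An open care
episode satisfies any duration requirement. Malformed patient records are
rejected with a logged diagnostic, never a crash.

## Statistics

* **Heterogeneity**: Pearson chi-squared without continuity correction,
  (r−1)(c−1) df. A zero marginal is an error for the bare test; inside the
  table builders a constant outcome column (e.g. no missingness anywhere)
  is reported as statistic 0, p = 1.
* **Trend**: Cochran–Armitage on k×2 tables, k ≥ 3, scores 0,1,2,...
  from the least-exposed category (the reported deprivation effect is "per
  tertile increase"). The statistic is invariant to affine score changes;
  the test-suite oracle is the independent identity X² = N·r² with r the
  Pearson correlation of score and outcome on the row-expanded data.
* **Odds ratios**: cross-product estimate with the Woolf interval
  `exp(ln OR ± 1.96·√(Σ 1/cell))`; no continuity correction by default, a
  zero cell raises an error that names the optional Haldane (+0.5) fix.
* **Logistic regression**: statsmodels GLM, binomial family, IRLS,
  deviance-change tolerance 1e-12, maximum 50 iterations. The tight
  tolerance makes grouped-binomial and row-expanded fits agree in both
  coefficients and covariance, and makes the single-covariate 2×2 fit
  match the closed-form odds ratio and Woolf SE to at least six
  significant figures. Separation is detected by diverging coefficients
  (|log-odds| > 30) or exploding Wald SEs; a non-converged fit refuses to
  report estimates.
* **Conventions**: reference levels are male sex, single marital status,
  schizophrenia diagnosis; age is dichotomised at 65 for regression while
  descriptive tables keep seven ten-year bands; deprivation enters
  regression as one ordinal 0/1/2 term. Analyses are complete-case per
  model term ("unknown" levels are dropped with the level order — and so
  the reference — explicitly preserved; pandas' `remove_categories` would
  silently re-sort them), and n is reported with every fit. P-values are
  printed to two decimals, "<0.001" below that threshold.

## Evaluation

Matching is one-to-one per document, greedy by leftmost-longest, requiring
status agreement plus span overlap (default) or exact spans. A predicted
annotation with the right span but wrong status counts as both a false
positive and a false negative. Precision and recall are undefined (None),
not zero, when their denominators are empty. The repo's regression gate on
the shipped synthetic gold corpus is precision ≥ 0.90 with recall below
precision under the abstaining rules — a policy threshold for rule
changes, not an external performance claim.

## The synthetic register

The generator emulates the data structure the analysis assumes, with
defaults fixed as the package's study conditions:

* **Demographics** drawn from the margins of a 12-month-care secondary
  mental-health SMI cohort: age bands (23/28/20/12/6/5/6% from 15–24 to
  75+), sex 52/48, marital 66/17/14/3% (single/cohabiting/separated-
  widowed/unknown), deprivation tertiles ~30/32/30% plus 7% unknown,
  diagnoses 43/4/25/28% (schizophrenia/schizoaffective/bipolar/other).
  Referrals are uniform over 2008–2011; 28% of episodes last ≥ 12 months.
* **Smoking model**: logistic in the regression covariates with
  coefficients ln(0.23) for age 65+, ln(0.62) female, ln(0.53) cohabiting,
  0 separated/widowed, ln(1.26) per deprivation tertile, ln(1.66)
  schizoaffective, ln(0.77) bipolar, ln(0.58) other, intercept 0.9 —
  chosen to give ~60% current smoking among ascertained patients. 35% of
  non-current smokers are past smokers.
* **Documentation model**: documents per patient ~ Poisson(5) floored at
  one, dated uniformly over the care episode; given an ascertainable
  patient, each document states smoking with probability 0.6. Phrasing
  mix: 15% deliberately out-of-lexicon (creating honest recall < 1), 10%
  ambiguous (conflicting cues; the abstaining engine skips them, the
  non-abstaining engine guesses), the rest standard; 15% of documents also
  carry a non-tobacco distractor. Structured entries exist for 18% of
  ascertainable patients, dated 0–30 days after referral.
* **Missingness mechanism**: a second logistic (intercept −1.0, female
  +0.47, bipolar +0.73, −0.22 per deprivation tertile) decides whether a
  patient's record ever states smoking. The documentation and missingness
  defaults were calibrated together so that observed 12-month-cohort
  coverage lands near 64% (≈36% missing) with the missingness patterned
  by sex, diagnosis and deprivation.

What the generator does **not** emulate: real note length, style or
vocabulary; longitudinal status change (one true status per patient);
inter-annotator disagreement; de-identification artefacts. Passing tests
therefore demonstrate internal correctness of rules, resolution and
statistics under the assumed structure — not performance on real clinical
text, which depends on lexicon fit to local phrasing.

## Problem sizes and seeds

The shared test register is n = 2,000 patients (~10,000 documents);
the missingness-realism check uses n = 8,000 so the configured 10-point
sex gap is detected with essentially full power; prevalence-recovery runs
at n = 10,000–20,000 within binomial sampling bounds. The statistical
property suites use 1,000 random tables for the trend-test oracle, 2,000
null tables for type-I calibration (3-s.e. band around 5%), and 100
replicates at n = 5,000 for Wald-coverage recovery of the generating
coefficients. All randomness flows through seeded `numpy` generators;
identical configurations produce byte-identical registers.

## Known limitations

* Bare mentions ("Tobacco use noted.") always abstain; a deployment that
  wants to count them as current can add the pattern as a current cue.
* Chain-collapsing of nearby candidates means two genuinely distinct
  mentions closer than `max_tokens` tokens merge into one annotation.
* The trend test and chi-squared tests are asymptotic; no exact tests are
  provided, and no imputation of missing status is attempted — missingness
  is described, not corrected for.
* Whether annotation should be mention-level or sentence-level is a
  genuine design fork; mention-level was chosen, with spans anchored on
  the lexical tobacco term.
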