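# Methods

## Scope and data model

`ordercast` models one decision: given an accepted psychiatric
treatment-order request, will the court grant it **entirely** or only
**partially**? Denied requests carry no entire/partial outcome; the
reader keeps them (for corpus statistics) and the modelling layer
filters them out, erroring if nothing modellable remains.

A judgment record holds sixteen variables: representation and
legal-aid status, age, sex, main and other diagnoses (free text),
symptom/behaviour text, substance use and substances, request type
(treatment vs treatment-and-housing), requested treatment text,
accessory requests, requested and granted durations in years, the
decision, and the acceptance extent. Files are RFC-4180 CSV with one
canonical English header per variable; a header map supports
alternative (e.g. French) headers. Invariants enforced on read: age in
[0, 130], durations in [0, 10], and extent `not_applicable` exactly
when the decision is denied.

## Semantic flags

Both flags are substring matches after normalization (lowercase, NFKD
accent stripping, whitespace collapse). No tokenization and no negation
handling: "denies non-compliance" still sets the flag — a known
limitation of keyword lexicons, kept deliberately simple so the flags
are auditable. The default lexicon is three severity terms
(schizophrenia, psychosis, bipolar disorder) and three non-compliance
terms (non-compliance, refused, discontinued); production lexicons
(e.g. bilingual ones) load from JSON and are never merged silently.
`compliance_flag = 1` means non-compliance evidence is present; rules
phrased in terms of compliance use its complement.

## The fuzzy layer

Mamdani-type, with three design commitments where the reference
description is open:

* **Conjunction = min t-norm** — the standard Mamdani choice for
  "AND".
* **Aggregation = normalized weighted mean** of crisp consequent
  values over fired rules, `Σwᵢsᵢvᵢ / Σwᵢsᵢ`. Normalizing keeps the
  score in [0, 1] for any weight assignment and makes a single fired
  rule return exactly its own crisp value, which is what the reference
  case profiles exhibit. A centroid-of-clipped-sets mode is out of
  scope.
* **Crisp consequent values** Low 0.17, Medium 0.50, Medium-High 0.65,
  High 0.85. These are calibration constants, not reported facts: they
  are chosen so the two reference profiles score exactly 0.85 (only
  the High/weight-1.0 severe-and-non-compliant rule fires) and 0.45
  (the Low/weight-1.0 compliant rule and the High/weight-0.7
  short-duration-legal-aid rule fire together:
  (1·0.17 + 0.7·0.85)/1.7 = 0.45). They are ordinary configuration,
  serialized with everything else.

Other numerical choices: the "high Burden_Score" condition of rule 6
is a crisp threshold at 0.6 (upper band of the Medium output set;
configurable); "short"/"long" durations are the Short/Long membership
degrees of the normalized requested duration, not crisp cut-offs;
binary antecedents contribute degrees in {0, 1}; if no rule fires the
score defaults to the neutral 0.5; category boundaries 0.4 and 0.7
belong to Medium; scores outside [0, 1] are a domain error.
Shouldered triangles (a = b or b = c) give degree 1 on the flat end.

The whole system — triangles, rules, weights, crisp values,
thresholds — round-trips through one JSON document, and the engine is
property-tested for exact agreement with a straight-line enumeration
of the ten rules, for score bounds (convex hull of fired crisp
values), for monotone response to any single rule's strength, and for
invariance to registry order.

## Features and scaling

The classifier sees ten features in fixed order (age, requested and
granted durations, legal aid, sex as female = 1, substance use,
severity flag, compliance flag, burden, expanded score). Age and
durations are passed in raw years — tree ensembles are invariant to
monotone rescaling — while the fuzzy layer consumes min–max-scaled
copies. Scalers are fitted on the training split only and persisted
with the model; a constant training feature degenerates to a constant
0.5 after scaling rather than erroring. When a single case is traced
without a trained bundle, reference scalers (age 18–90, duration
0.5–5 years) stand in.

The granted duration is both a feature and determined together with
the outcome; it is retained by default because the modelled workflow
retains it, and `exclude_time_granted=True` removes it for
leakage-free variants.

## Classifier and evaluation

`RandomForestClassifier` with 100 trees and
`class_weight='balanced'`; no other tuning (defaults are recorded in
the bundle). Positive class = entire acceptance. Precision/recall with
empty denominators report 0 with a logged warning. The 70/30 split
allocates per-class test counts by largest remainder against
`round(0.3·n)`, which keeps every class's test share within one case
of 30% — a guarantee the generic scikit-learn splitter does not make —
and yields the documented 7/3 split on 10 balanced cases. 10-fold
stratified cross-validation uses `StratifiedKFold` and refits the
scalers inside each training fold. All randomness flows from one
integer seed through named sub-streams (split/train/cv/synth), so
reports are byte-identical across runs.

The Pearson table covers only the numeric, monotone predictors
(expanded score, burden, requested and granted durations); entries
against a constant column are reported as undefined (NaN), never 0.

## Synthetic generator

The generator emulates a one-year corpus of roughly 176 judgments:
70% severe diagnoses, 60% documented non-compliance, 40% substance
use, 40% female, 95% represented (70% of those by legal aid), 5%
denied requests, ages ~N(45, 15²) clipped to 18–90, requested
durations uniform on {0.5, 1.0, …, 5.0} years. Texts are assembled
from fixed template pools partitioned by the default lexicon, so the
flags recover the generator's latent severity/compliance bits exactly
— synthetic data is *invertible*, which is what makes end-to-end
recovery tests meaningful, and is precisely what real clinical prose
is not. Passing tests therefore demonstrate pipeline correctness, not
robustness to real-world narrative variation, negation, or French
legal language.

Granted duration is `requested × F`, `F ~ Beta(a, b)` with `(a, b)`
solved in closed form from the configured mean fraction (0.75) and
target requested/granted correlation (0.80), using
`corr(R, RF) = μ_F σ_R / sqrt(σ_F² E[R²] + μ_F² σ_R²)`.

The outcome is logistic in the burden composite:
`P(entire) = expit(β0 + β1·burden + β2·t_norm)` plus independent label
noise. Defaults β1 = 6, β2 = −1, β0 = −4.2 give ≈30% entire
acceptances (β0 solved numerically against the covariate
distribution). Note the default process is intentionally *hard*: the
burden atoms are dense near the decision boundary, so the Bayes
accuracy is only ≈0.73 and fitted models plateau near 0.70 — a
realistic regime. Parameter-recovery tests instead use the steep-slope
limit (β1 = 1000 centred at burden 0.585, 5% label noise), where
labels are a noisy deterministic function of reconstructable features
and the fitted pipeline reaches ≈0.94 held-out accuracy. In that
regime the Gini mass concentrates on the burden-linked features; note
that the composite `burden_score` feature absorbs most of the credit
of its own components (requested duration in particular), so recovery
is asserted on the group's combined importance plus the individual
ranks of `burden_score` and `severity_flag`, not on every component
ranking highly by itself.

## Problem sizes

Test and demonstration runs use what the statistics require and no
more: worked profiles are single cases; oracle-equivalence sweeps use
1000–1500 random profiles; recovery fits use n = 1000 records;
correlation targets are checked at n = 10 000, where ±0.03 is ≈4
standard errors; stratification bounds are exercised across 100 random
datasets of 20–160 cases.

## Known limitations

Keyword flags have no negation or context handling; the default
lexicon is English while real Quebec judgments are largely French
(bilingual lexicons are configuration); rule weights are fixed by
expert assignment, not learned; the weighted-mean defuzzification
bounds attainable scores to [0.17, 0.85] under the default registry;
the granted-duration feature leaks decision information unless
excluded; and synthetic realism is explicitly a non-goal — the
generator validates machinery, not jurisprudence.
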