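# Methods

## Data model

Four flat tables abstract a primary-care EMR extract: patients (year of
birth, gender, site), encounters (date, in-person flag), diagnoses (ICD-9
code, date, source ∈ {encounter_diagnosis, billing, health_condition},
optional encounter link) and prescriptions (drug identifier, date). The
on-disk format is one UTF-8 CSV per table, empty string for missing,
ISO-8601 dates; `src/adhd_emr/schema.yaml` is the column dictionary. Codes
are stored verbatim and normalised (strip, uppercase) at read time. Readers
reject rows violating type constraints (counts kept in provenance) and
refuse datasets with broken referential integrity; write-then-read is the
identity on valid datasets and is property-tested.

Patients carry a year of birth only, so all ages are year arithmetic
(`study_year − birth_year`). Boundary patients (ages 4, 17/18, 34/35, 64/65)
can therefore shift by up to one year relative to exact-birthdate ages; this
is a property of the data model, not a bug, and it is applied consistently in
both the age gate of the case definition and the stratification.

## Case definition

A patient is an ADHD case *as of Dec 31 of a study year* when:

* age in that year ≥ 4 (configurable);
* no diagnosis code up to the cutoff matches an exclusionary prefix;
* and either ≥ 1 qualifying visit day plus ≥ 1 ADHD-related prescription, or
  ≥ 2 qualifying visit days.

A qualifying visit day is a distinct calendar date with an in-person
encounter carrying a code matching the ADHD prefix ("314" matches "314",
"314.0", "314.01", …). A diagnosis row qualifies if its linked encounter is
in-person, or, when unlinked (e.g. billing rows), if the patient had an
in-person encounter on the same date — billing codes alone, with no
encounter-linkable date, never constitute a visit. Two codes on one day
count once.

Deliberate semantic choices:

* **Prefix matching** is the standard reading of "code 314" and is
  configurable (`adhd_code_prefix`).
* **Medication matching** accepts an ATC prefix (default N06BA, the
  centrally acting sympathomimetics) or a normalised name list
  (methylphenidate, amphetamine salts, lisdexamfetamine, atomoxetine,
  guanfacine XR). No ordering between coded visit and prescription is
  required.
* **Exclusion codes** block case status wherever they appear in the record
  up to the study-year cutoff; no proximity to the ADHD codes is required.
  The shipped default list (ICD-9 290, 295, 299, 317–319: dementia,
  schizophrenia, pervasive developmental disorders, intellectual
  disability) is illustrative — real deployments substitute their governed
  list via `exclusion_code_list`.
* **Lifetime semantics**: yearly case status uses all records up to Dec 31
  of the study year, never requiring ADHD activity *within* the year. With
  accruing records this makes case status monotone over years (absent
  exclusion codes), which matches how cumulative documentation behaves; a
  year-active definition would estimate treated prevalence instead and
  would need only a date filter.

Two implementations are kept in lockstep: a plain per-patient reference
(`classify_patient`) and a vectorised batch version (`find_cases`) that
handles 10^5-patient populations in about a second. Tests compare them to
each other and to an independently written brute-force oracle on randomized
datasets, and check monotonicity (extra evidence never un-flags) and
temporal consistency.

## Denominators and strata

The practice population for year Y is the two-year contact group: any
patient with an encounter in Y or Y−1 and a valid year of birth and gender.
Any encounter counts (in-person or not): contact, not visit modality, is
what defines an active patient; requiring in-person contact here would
conflate the denominator definition with the case definition's visit rule.
Strata are 4–17, 18–34, 35–64 by gender; under-4s and seniors (65+) belong
to no stratum. Patients with missing/other gender are excluded from the
population (validity of both demographic fields is part of the denominator
definition).

## Validation statistics

From a review design of "all flagged + a sample of unflagged", PPV and NPV
are binomial proportions; intervals are exact Clopper-Pearson (Beta
quantiles), implemented directly and cross-checked in tests against
statsmodels' independent implementation and by a 10,000-replicate coverage
simulation. Sensitivity, specificity and the clinic's true prevalence come
from the misclassification identities

    π = p·PPV + (1−p)·(1−NPV),  Se = p·PPV/π,  Sp = (1−p)·NPV/(1−π),

locked by a property test: forward-simulating (p, PPV, NPV) from any
informative (π, Se, Sp) and deriving back is the identity to machine
precision.

The derived Se/Sp have no exact interval in this design; `se_sp_uncertainty`
propagates binomial uncertainty of (TP | n flagged), (TN | n sampled) and
(flagged | clinic size) by a seeded parametric bootstrap with percentile
intervals. This is the package's own uncertainty treatment; externally
quoted intervals for derived indices may use other propagation methods and
are not reproduced as golden values.

A practical pitfall made explicit in the API: deriving Se/Sp from predictive
values *rounded for reporting* (e.g. 98.0%/95.0%) can differ grossly from
deriving them from the raw counts (95.9%/96.3% → Se 24.9% vs 19.9%), because
at low apparent prevalence the derived sensitivity is dominated by 1−NPV.
`validity_from_counts` therefore computes from counts by default and takes
`ppv_override`/`npv_override` explicitly, never silently.

## Prevalence adjustment

Default method is the Rogan-Gladen inversion π = (p + Sp − 1)/(Se + Sp − 1),
truncated to [0, 1] (truncations logged), requiring an informative algorithm
(Se + Sp > 1). Se/Sp are properties of the algorithm and transport to
populations whose prevalence differs from the validation clinic's; the
direct map π = p·PPV + (1−p)(1−NPV) is retained as `ppv_npv_direct` with the
documented caveat that predictive values are prevalence-dependent, so it is
strictly valid only at the validation clinic's prevalence. The two methods
coincide exactly when the target p equals the clinic's apparent prevalence
(property-tested).

Adjusted intervals transform both endpoints of the observed proportion's
exact binomial interval through the same map. This is an approximation: it
preserves exactness with respect to sampling of the flagged count but
ignores uncertainty in the validity indices themselves, so it understates
total width when the validation study is small relative to the target
population.

Gender ratios are male:female adjusted prevalence, displayed to one decimal
as "x:1"; a zero or missing female estimate flags the row rather than
dividing.

## Synthetic data generator

`synth.generate` emulates the features the pipeline depends on, with one
seeded RNG and bit-identical output per (config, seed):

* age structure at the reference (last) year from fixed bands (4% under 4,
  17% 4–17, 24% 18–34, 47% 35–64, 8% seniors), 43% male — an adult-heavy,
  female-leaning roster typical of primary care;
* true ADHD status drawn per (age group × gender) stratum; defaults range
  from 9.5% (boys 4–17) down to 5.1% (women 35–64), i.e. primary-care-style
  levels with the usual male excess shrinking with age;
* a roster period per patient (uniform start year through the last year) and
  Poisson(3) encounters per active patient-year, 90% in-person — this makes
  two-year-contact denominators non-trivial and growing over calendar time;
* typical true cases leave a qualifying structured footprint (half via one
  coded day + prescription, half via 2–4 distinct coded days);
  **specialist-managed** true cases (default rate 9/245, the missed-case
  fraction the 492-chart validation design exhibits) leave *no* structured
  ADHD codes or medications; **rule-out** non-cases (default 1%) get exactly
  one coded visit and no prescription;
* 1% of patients carry invalid demographics (missing year of birth or
  gender), 0.5% an exclusionary code.

The rule-out and invalid-demographic base rates have no published
population-level counterpart; they are fixed at plausible primary-care
magnitudes and are configuration, not estimates. With both misclassification
mechanisms disabled the case finder is provably perfect against ground truth
(closure test).

`synth.make_validation_fixture` is different in kind: an *engineered* clinic
of 19,683 patients constructed so the case finder flags exactly 246
patients, of whom 236 are true cases, while a 246-patient unflagged review
sample contains the 9 specialist-managed missed cases and 237 true
non-cases — the canonical validation 2×2 (TP=236, FP=10, TN=237, FN=9). Its
10 false positives carry two 314-coded billing visit days (intensive
rule-out work-ups), unlike the generator's single-visit rule-outs, because
flagged false positives are what a review of flagged patients observes.
Decoy patients who satisfy the visit rules but fail the age gate or carry
exclusion codes are planted so that the flagged count exercises every
clause. The construction is structural: the seed varies ages, dates and code
variants but never the counts. The confusion matrix returned is recomputed
by running the case finder, not asserted.

What the generator does **not** model: free-text notes (so nothing here says
anything about NLP-based ascertainment), comorbidity structure, dosing,
within-family correlation, site heterogeneity, or secular drift in coding
practice. Passing tests therefore demonstrate the *estimators'* correctness
under known misclassification mechanisms, not the clinical validity of the
case definition on any real population.

## Parameter recovery study

`studies.parameter_recovery_study` estimates validity indices by exhaustive
review of one synthetic clinic (n = 50,000; with a full review, deriving
Se/Sp from PPV/NPV and apparent prevalence coincides algebraically with
measuring them directly) and applies the Rogan-Gladen correction to an
independently generated 100,000-patient population with a flat 7% true
prevalence over a 2014–2015 window. The estimand is the realized case
fraction among each stratum's practice-population members. Acceptance-level
checks: truth falls inside every stratum's adjusted 95% CI, and the adjusted
estimate beats the observed one in ≥ 90% of the nine strata. The two-year
window keeps the study inside a laptop-scale compute budget while leaving
per-stratum case counts in the hundreds-to-thousands range.

## Numerical and degenerate-input choices

* Clopper-Pearson endpoints are closed at 0 and 1 (k=0 → lower 0; k=n →
  upper 1).
* `derive_se_sp` rejects p ∉ (0,1), PPV/NPV ∉ (0,1], and degenerate implied
  π; derived Sp is clipped at 1 when inconsistent rounded inputs push it
  marginally above.
* Rogan-Gladen adjustment raises on Se+Sp ≤ 1 and truncates π to [0,1]
  (observed p below the false-positive floor 1−Sp maps to 0).
* Bootstrap replicates with degenerate implied prevalence are dropped;
  n_boot < 1000 is rejected.
* Zero-denominator strata and undefined gender ratios are flagged rows, not
  exceptions.
* Display rounding: percentages to one decimal for validity indices, two
  decimals in prevalence tables.

## Known limitations

* Endpoint-transformed adjusted CIs ignore validity-index uncertainty (see
  above).
* Lifetime case semantics make early study years under-ascertain relative
  to truth when records only begin accruing at roster start — visible in the
  synthetic world's rising yearly counts; real multi-year extracts carry
  history predating the study window, softening this.
* Year-arithmetic ages shift boundary patients by up to one year.
* The generator's mechanism rates beyond the specialist-managed miss rate
  are plausibility choices, so absolute synthetic prevalence trajectories
  are illustrative, not calibrated.
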