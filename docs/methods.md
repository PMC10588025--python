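# Methods

## Problem and pipeline

`rxmine` analyses co-prescription patterns of type 2 diabetes mellitus
(T2DM) patients in pharmacy-claims data that carry no diagnosis codes. The
pipeline has five stages:

1. **Ingestion & mapping** — claims rows (one per dispensed drug) are read
   from delimited text; patients with any missing age or gender are removed
   entirely (listwise deletion, justified by a missing-completely-at-random
   assumption); a unique patient ID is formed from the insurance ID and
   serial; every record is joined to the five ATC hierarchy levels of its
   national drug code, the prescriber's specialty, and the patient's age
   category (Young < 30 ≤ Middle-Aged < 45 ≤ Old).
2. **Phenotyping** — a rule framework labels T2DM patients: a prescription
   containing an A10 ("Drugs Used in Diabetes") product, excluding insulin
   syringe/device codes, written by a general practitioner, internist, or
   endocrinologist, and no competing indication among four exclusion
   branches for patients under 30 (T1DM in males: any insulin; T1DM in
   females: any non-human insulin; PCOS: metformin from gynecology;
   pregnancy: human insulin without any oral anti-diabetic in a non-PCOS
   prescription). A10 records of non-T2DM patients are then censored.
3. **Transactions** — per patient, the deduplicated set of ATC codes
   truncated to a chosen level (1–5), overall and per gender × age-category
   stratum including margins.
4. **Mining** — from-scratch FP-Growth over the baskets, then association
   rules A → b (single-item consequents) with support σ/N, confidence,
   lift, and a diabetic-prevalence indicator σ/n_diabetic.
5. **Reporting** — diabetes-anchored filtering (antecedent entirely under
   A10, consequent outside A10), a strict lift > 2.0 floor, sorting by
   prevalence (level 2) or lift (levels 3–5), truncation to the top 30, and
   a support × confidence threshold grid search.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `min_support` | 0.0001 | minimum rule/itemset support as a fraction of all patients |
| `min_confidence` | 0.1 | minimum P(consequent \| antecedent) |
| exclusion age cutoff | 30 y | upper age bound of the four exclusion branches |
| lift floor | 2.0 (strict) | report admission threshold |
| top k | 30 | report truncation per level |

Support counting is non-strict at the threshold: an itemset is frequent when
its count reaches `ceil(min_support × N)`, the convention of classic
frequent-pattern mining. N always includes patients whose entire basket was
censored away, so support denominators equal the analyzed cohort size.

## Design choices where the design was open

- **Criteria conjunction.** The drug and prescriber criteria are evaluated
  on the *same* prescription (a "qualifying prescription"), the stricter
  and clinically more sensible reading; `per_prescription=False` relaxes to
  independent evaluation across the history. The strict labels are provably
  a subset of the loose ones (tested).
- **Missing demographics.** "Missing age and gender" is read as *either*
  field missing (drop the patient); `missing_rule="all"` gives the
  literal-AND variant.
- **Conflicting ages.** A patient with differing ages across records gets
  the earliest record's age; with no date column this is the minimum.
- **Insulin syringes.** ATC has no device class, so syringes are handled as
  a configurable national-code exclusion list that blocks the drug
  criterion but still censors with A10.
- **Human insulin** is identified by generic-name match with an optional
  explicit ATC list.
- **Lift** is the standard Conf(A→B)/Supp(B); it is computed from exact
  integer counts, as are all metrics, so the identities
  support = σ/N, confidence = support/Supp(A), lift·Supp(B) = confidence
  hold to 1e-12 (they are checked on every mined rule).
- **Unmapped drug codes** drop the record, not the patient, and are
  counted; unknown prescriber codes are flagged `"Unknown"` rather than
  dropped.
- **Tie-breaking** in reports (confidence descending, then antecedent code
  order) and in the FP-tree item order (descending count, lexicographic)
  is fixed for determinism; any total order is equally correct.
- **Stratified mining** uses stratum-local N and n_diabetic, the only
  self-consistent choice when metrics are compared within a stratum.

## The synthetic generator

Real claims extracts of this kind are not redistributable, so cohorts are
simulated. Each patient draws a latent profile — T2DM (default 10%), then
gender and age category conditionally (diabetics ~63% female, ~77% old),
then comorbidities: hypertension, dyslipidemia, hypothyroidism
(female-skewed), neuropathy (old-skewed), and, among young non-diabetics,
mutually exclusive confounders (T1DM, PCOS, pregnancy). Prescription count
is 1 + Poisson(λ), λ = 4 for diabetics and 2 otherwise. Per prescription,
each formulary drug enters independently with probability
`1 − ∏_c (1 − p_{d|c})` over the active conditions; prescriber specialty is
drawn per prescription from a profile-specific distribution, with
gynecology forced on PCOS-metformin and pregnancy prescriptions. An
always-active "baseline" condition supplies everyday primary-care drugs so
nearly all patients appear in the dispensing table. A configurable fraction
of patients (default 2%) has age or gender blanked across their history.

Condition→drug probabilities were calibrated once so that the diabetic
co-prescription prevalences of the four classic comorbidity classes (C10,
C09, B01, C07) fall near the magnitudes and ordering reported for large
insured urban populations (~56/49/36/30%); this calibration is cosmetic and
no test asserts those values.

**Closed-form oracle.** Because drug draws are independent across drugs
given the profile and the prescription count m, the probability a patient
ever holds ATC code c is `1 − B_c (1 − q_c)^m`, where `q_c` aggregates the
per-prescription probabilities of condition-driven drugs under c and `B_c`
the miss probability of the patient-level background drugs. Marginalizing
over profiles (enumerable) and the Poisson prescription count (truncated at
60 terms) yields exact support/confidence/lift for any same-level rule.
Two background drugs (cetirizine R06, amoxicillin J01) are sampled once
*per patient* rather than per prescription: a shared random prescription
count would otherwise correlate any two per-prescription drugs, whereas
patient-level sampling makes the planted-independent pair's lift exactly 1.

**Recovery tests** mine an *uncensored* cohort (latent truth labels, no
missing demographics) so that mined denominators equal the closed form's,
and require mined lift within 3 Monte-Carlo standard errors of the closed
form. The SE uses the delta-method bound
`lift · sqrt(1/σ_AB + 1/σ_A + 1/σ_B)`, which drops the (negative)
covariance corrections and therefore slightly overstates the SE.

**What the generator does not emulate:** longitudinal dosing and
refill adherence, prescription dates (hence no temporal phenotyping),
realistic formulary breadth (23 drugs vs thousands), multi-drug ATC
classes at level 5, and correlated prescriber-patient affiliation. Passing
tests therefore demonstrate correctness of the *pipeline mechanics and
estimators* under the assumed generative structure, not fidelity of any
clinical conclusion drawn from real data.

## Sizes, numerics, degenerate inputs

Unit tests run on a 3,000-patient cohort; parameter recovery and the
acceptance script use 50,000 patients, where generation plus full mining
takes a few seconds. Mining is exact integer arithmetic until emission;
there are no tolerances inside the miner. Degenerate inputs are defined:
empty claims files yield empty frames, empty transaction sets mine to
nothing, an all-censored patient keeps an empty basket in N, prevalence on
a stratum without diabetics raises, and the brute-force oracle refuses
instances with more than 20 frequent items.

## Known limitations

- Phenotyping misses diabetics who never received a qualifying
  prescription (~1% of diabetics at the default generator settings); the
  truth table flags these (`no_qualifying_rx`), and label-accuracy tests
  require every miss to be so flagged.
- With the default `min_support = 0.0001`, strata smaller than 10,000
  patients have a support threshold of one transaction, so rule counts
  explode on small strata — faithful to the method, but users should raise
  the threshold when mining small segments.
- The closed-form oracle covers rules whose items map to formulary drugs;
  it does not model the censoring step (recovery tests bypass it by
  design).
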