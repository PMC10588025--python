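# rxmine

Co-prescription pattern mining for type 2 diabetes mellitus (T2DM) from
pharmacy-claims data.

Insurance claims often record every dispensed drug but no diagnosis (ICD)
code, so "who is diabetic" and "what is co-prescribed with diabetes drugs"
must both be inferred from prescriptions alone. `rxmine` implements that
analysis end-to-end for epidemiologists and health-services researchers:

- **rule-based T2DM phenotyping**: a patient is labeled T2DM when some
  prescription contains an ATC class A10 drug (excluding insulin
  syringes), was written by a general practitioner, internist, or
  endocrinologist, and none of four competing-indication branches fires
  for patients under 30 (T1DM in males/females, PCOS metformin from
  gynecology, pregnancy on human insulin); A10 drugs are censored from
  non-T2DM patients afterwards;
- **hierarchical transactions**: one deduplicated basket of ATC codes per
  patient at any level of the ATC tree (A10 → A10B → A10BA → A10BA02),
  overall and per gender × age stratum;
- **from-scratch FP-Growth** association-rule mining. For a rule A → B
  over N patients with σ(A→B) patients holding both sides:

  Supp(A→B) = σ(A→B)/N,  Conf(A→B) = Supp(A→B)/Supp(A),
  lift = Conf(A→B)/Supp(B),  prevalence = σ(A→B)/n_diabetic,

  the last being the fraction of diabetic patients co-prescribed the
  rule's drugs;
- **reporting conventions**: diabetes-anchored rules (A10-only antecedent,
  non-A10 consequent), strict lift > 2.0, top 30 per level, sorted by
  prevalence at level 2 and by lift at levels 3–5; plus a
  support × confidence threshold grid search;
- **a synthetic claims generator** with planted comorbidity structure,
  confounder subpopulations, and closed-form expected rule metrics, used
  throughout the test suite for parameter-recovery checks.

See `docs/methods.md` for the model, assumptions, and design decisions.

## Worked example

Simulate a cohort, phenotype it, and report diabetes-anchored rules:

```sh
rxmine simulate --n-patients 2000 --seed 7 --out demo
rxmine label --claims demo/claims.csv --drug-map demo/drug_mapping.csv \
  --specialty-map demo/specialty_mapping.csv --out demo/labels.tsv
```

prints the labeling log:

```json
{"n_patients": 1735, "n_t2dm": 192, "n_t1dm_male": 3, "n_t1dm_female": 3,
 "n_pcos": 3, "n_pregnancy": 6, "n_censored_a10_records": 46,
 "ingestion": {"n_input": 8392, "n_dropped_missing_demographics": 141,
 "n_dropped_unmapped_drug": 0, "n_retained": 8251}}
```

Of 2,000 simulated patients, 1,735 survive demographic filtering and
appear in the dispensing table, 192 (~11%) are labeled T2DM, 15 young
patients hit an exclusion branch, and 46 A10 records of non-T2DM patients
were censored. Then:

```sh
rxmine report --claims-in demo/claims.csv --drug-map demo/drug_mapping.csv \
  --specialty-map demo/specialty_mapping.csv --out-dir demo/reports
head -4 demo/reports/rules_level2.tsv
```

```text
lhs   rhs  joint_count  support   confidence  lift    prevalence
A10   C10  107          0.06167   0.55729     2.7237  0.55729
A10   C09  90           0.05187   0.46875     2.0032  0.46875
A10   C03  74           0.04265   0.38542     2.3713  0.38542
```

Reading the first row: 107 patients hold both a diabetes drug (A10) and a
lipid-modifying agent (C10); 55.7% of patients on diabetes drugs — and,
here, 55.7% of labeled diabetics — also received a statin-class drug, 2.7
times the rate expected if the two classes were prescribed independently.
`rxmine mine --stratum female,Old ...` repeats the analysis in one
demographic stratum, and `rxmine sweep` tabulates itemset/rule counts over
a threshold grid.

The same pipeline is available as a library: `rxmine.simulate` →
`rxmine.prepare` → `PipelineResult.transactions(level)` →
`rxmine.mine_rules` → `rxmine.rank_and_truncate`.

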