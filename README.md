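# scdcsurv

Population-based sickle cell disease (SCD) surveillance tooling: multi-source
case finding, record linkage and deduplication into a master person index,
tiered case classification, and prevalence reporting — exercised end to end on
a seeded synthetic-data generator with known ground truth.

## The problem

No single data source sees the whole SCD population. Newborn screening (NBS)
captures laboratory-confirmed genotypes but only for in-state births since the
program began; specialty clinics see the patients in care; Medicaid/CHIP
claims and hospital/emergency-department discharges carry diagnosis codes for
whoever used services; death certificates close out the cohort. State
surveillance programs therefore link all five sources on personal identifiers,
deduplicate, and classify each person against a tiered case definition.
Real state data are protected health records, so this package ships a
generator that emulates the structure those programs face — overlapping
partial source coverage, noisy identifiers, diagnostic miscoding, duplicate
billing, and in/out migration — and every stage of the pipeline is validated
against the generator's ground truth.

## Methods at the core

* **Case finding** uses the ICD-9-CM / ICD-10-CM code sets for SCD
  (282.41–282.69 excluding trait; the D57 family with wildcard suffixes) and
  tracks sickle cell trait (282.5, D57.3x) separately.
* **Record linkage** is a deterministic exact-match cascade (SSN+DOB, or
  name+DOB+sex) followed by Fellegi–Sunter probabilistic scoring: each
  candidate pair (found by blocking on Soundex(surname)+birth year or SSN)
  gets a weight `w = Σ_f log2(m_f/u_f)` over agreeing fields f (and
  `log2((1−m_f)/(1−u_f))` for disagreeing ones), thresholded into
  match / review / non-match; names agree under a Jaro–Winkler cutoff.
  Match pairs are closed transitively into person clusters.
* **The master index** is hub-and-spoke: the deduplicated person table (hub)
  keeps crosswalk links to every source record (spokes). It is built
  confirmed-sources-first (NBS + clinic), then administrative sources
  restricted to persons with at least one SCD/trait-coded encounter, then
  merged; death certificates attach last and never create persons.
* **Case classification**: CONFIRMED (laboratory evidence), PROBABLE
  (unconfirmed NBS result, lab-less clinical diagnosis, or an SCD code —
  excluding trait — on ≥3 distinct service dates within a rolling 1826-day
  window), POSSIBLE (any other coded encounter history; retained but never
  reported), NONE.
* **Prevalence reports**: cumulative and annual counts of confirmed+probable
  persons by source with percent-of-deduplicated-total cells (half-up,
  1 decimal) and person-years; annual counts apply a migration adjustment
  (evidence in year Y, or both before and after Y, and not dead before Y).
  Genotype/sex/pediatric strata and truth-based sensitivity / specificity /
  PPV / NPV round out the evaluation.

## Worked example

```bash
cat > config.yaml <<EOF
generator:
  n_population: 2000
  scd_prevalence: 0.02
  seed: 42
EOF
scdcsurv generate --config config.yaml --out sources
scdcsurv build    --config config.yaml --sources sources --out index
scdcsurv classify --config config.yaml --sources sources --index index
scdcsurv report   --sources sources --index index --mode cumulative
scdcsurv evaluate --sources sources --index index
```

The generator emits 7 NBS, 32 clinic, 611 Medicaid, 410 hospital/ED and 81
death records for a 2,000-person population observed 2004–2018 (about 40 true
cases at 2% prevalence). Building the index yields 68 persons (the cases plus
miscoded non-cases; the 80 unmatched deaths are non-cases never seen by any
other source, which by design cannot enter the index). Classification prints

```
{"CONFIRMED": 25, "POSSIBLE": 24, "PROBABLE": 19}
```

and the cumulative report

```
            source  confirmed  probable  total  pct_of_dedup_total person_years
               NBS          7         0      7                15.9
            CLINIC         23         9     32                72.7
          MEDICAID         14         8     22                50.0          250
       HOSPITAL_ED         19        10     29                65.9          229
DEDUPLICATED_TOTAL         25        19     44               100.0
```

— each source captures only a partial, overlapping slice of the 44 reported
(confirmed + probable) persons, which is exactly why the sources must be
linked. POSSIBLE persons (mostly trait-coded non-cases) are retained in the
index but excluded from the report. `evaluate` scores the run against the
generator's truth:

```
{"sensitivity": 1.0, "specificity": 0.95, "ppv": 0.86, "npv": 1.0,
 "linkage_precision": 1.0, "linkage_recall": 0.987, "linkage_f1": 0.993, ...}
```

The false positives are miscoded non-cases that legitimately satisfy the
probable tier's claims-only clause — the inherent trade-off of a
claims-based case definition.

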