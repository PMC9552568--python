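# Methods

This note documents the models, parameters and design choices behind the
package: what the synthetic generator emulates, how the linkage engine and
case definition are specified, what the reports compute, and where open design
questions were settled.

## Synthetic surveillance data

The generator draws a closed population observed over a surveillance period
(default 2004–2018) and emits the five source files a state program links.

**Population model.** Disease status is Bernoulli per person
(`scd_prevalence`, default 0.02 — a deliberately enriched prevalence so that a
few-thousand-person population yields a workable case count; true population
prevalence of SCD is an order of magnitude lower). Genotypes among cases
follow `genotype_props`, default (0.63, 0.08, 0.27, 0.02) for
HbSS/HbS-β⁰-thalassemia, HbS-β⁺-thalassemia, HbSC and other SCD — the
distribution reported by mature state programs for their 2018 confirmed
cohort. Birth dates are uniform from `max_age_at_start` (60) years before the
period to its end; sex is 50/50. Death is an annual in-period hazard
(0.003/yr); pre-period deaths are not simulated because such persons emit no
records and are invisible to any surveillance design. Residence follows an
annual memoryless chain (out-migration 0.02/yr, return 0.30/yr, 95% initially
in state); a person out of state in year Y emits no records dated in Y, which
is precisely the situation the annual migration adjustment must handle.

**Source emission.** Coverage acts at the person level: an eligible case is
captured by NBS with probability 0.90 (eligible = born in state, in-period,
after the NBS start year), reported by a clinic with probability 0.60, and is
Medicaid-enrolled / hospital-using with probability 0.70 / 0.75 for the whole
period. Encounter counts per in-state person-year are Poisson (Medicaid mean
2.0, hospital/ED 1.0, scaled by the alive-and-resident fraction of the year),
each encounter carrying one or two genotype-appropriate diagnosis codes —
ICD-9-CM before October 2015, ICD-10-CM after. A hospital encounter is also
billed to Medicaid on the same date with probability 0.10 (duplicate
billing), exercising the distinct-date rule. NBS results carry confirmatory
testing with probability 0.95, clinic reports laboratory confirmation with
probability 0.90; these drive the confirmed-vs-probable split among true
cases.

**False-positive mechanisms.** 1% of non-cases accrue one or two miscoded
encounters (80% trait codes, 20% true SCD codes), populating the possible
tier with persons who do not have SCD — the situation validation studies of
claims-based definitions report. Another 1% accrue only innocuous chronic-
condition codes (background noise that the administrative scope filter must
exclude), and 0.2% receive a false lab-less clinic report.

**Identifier noise.** Every emitted record's identifiers pass independently
through the corruption model: per-field probabilities of a one-character
typo (names 5%/3%, SSN 2%, ZIP 5%), surname substitution from the fixed name
pool (2%), day/month transposition (2%, applied only when the result is a
valid date) or small day shift (1%) in the date of birth, and missingness
(SSN 15%, ZIP 5%, sex 2%, names/DOB 1%). At most one action fires per field
per record; missing values are represented as nulls, never sentinels. The
name pools and typo model are fixed package assets so linkage difficulty is
stable across runs. The identifier-quality profile is uniform across sources
(real programs see source-specific quality; the rates are per-field config if
a study needs that).

**What the generator does not emulate** — and hence what passing tests do not
show about real data: geographic detail, race/ethnicity, realistic SSN
issuance structure, within-person identifier drift over time (name changes at
marriage), source-specific identifier quality, twins/family clustering (a
hard real-world linkage confounder), and realistic (i.e., much lower)
population prevalence. Linkage F1 on this generator is an engineering
regression property, not an estimate of real-world linkage accuracy.

`GeneratorConfig.noiseless()` is the analytically checkable limit — full
coverage, zero corruption, zero miscoding, confirmation probability 1, no
migration — in which the pipeline must recover the truth exactly.

## Diagnosis-code classification

Code sets ship as a plain-text table (system, code, category, wildcard flag).
ICD-10 family rows ("D57.0X") are wildcard prefixes: the prefix plus any
suffix, including none. Trait (282.5, D57.3 and its extensions) is checked
before the SCD prefixes so D57.31 never falls into the D57 family row; bare
D57 with no fourth character classifies as SCD (it is its own table row).
Codes arriving without decimal points are normalized (point inserted after
three characters) before classification; malformed codes and unknown code
systems raise, naming the offending input — schema drift should fail loudly.
ICD-10 subcodes introduced after the code table's vintage (e.g., D57.81x
subtypes) are covered by the prefix rule by construction.

## Linkage engine

Parameters are configuration with documented defaults, not estimates (EM
estimation of m/u is out of scope by design; the engine stays deterministic
and auditable):

| field | m | u | rationale |
|---|---|---|---|
| first_name | 0.92 | 0.01 | typo model leaves most names agreeing at JW ≥ 0.85 |
| last_name | 0.92 | 0.005 | substitution + typo; rarer coincidental agreement |
| dob | 0.95 | 0.001 | transposition/shift/missing ≈ 4–5% |
| ssn | 0.97 | 1e−5 | near-decisive when present |
| sex | 0.98 | 0.5 | two-valued, nearly uninformative |
| zip | 0.90 | 0.01 | typo/missing 10%; ~80 values in the pool |

Agreement weights are log₂ likelihood ratios; missing fields contribute 0.
Thresholds default to 10 (match, inclusive) and 4 (non-match below); the
band between stands in for clerical review and resolves by policy — default
treats review as non-match, favouring precision, the conservative
auto-linking stance of production registries. Name agreement uses
Jaro–Winkler at cutoff 0.85 (survives single typos; integer-halved
transposition count, the convention of the standard C implementations).
Deterministic rules (exact SSN+DOB; exact first+last+DOB+sex) match
regardless of weight. Blocking on (Soundex(surname), birth year) and (SSN) is
mandatory above a 2,000-record guard; an unblocked mode exists for tests.
Within-source deduplication runs the identical engine before any cross-source
linking.

## Master index

Build order is fixed: per-source dedup → confirmed-source index (NBS +
clinic) → administrative index (claims/hospital entities having ≥1 SCD- or
trait-coded encounter; uncoded entities are out of surveillance scope and
tracked separately) → merge → death certificates last. A death record can
set a death date but never creates a person (a person known only from a death
certificate is unverifiable and stays in the exceptions log — a design
choice, flagged for review). Person uids are SHA-1 hashes of the sorted
member record ids at first creation; a rerun with a prior index adopts the
(smallest) previously issued uid for any cluster containing previously
indexed records, so incremental runs never rename, and linkage monotonicity
(edges only accumulate as records are added under unchanged config)
guarantees they never split. Demographics resolve field-by-field from the
highest-priority source holding a value (NBS > clinic > Medicaid >
hospital/ED > death), plurality-voted within a source with deterministic
tie-breaks; genotype comes only from the laboratory-bearing sources and
cross-source genotype disagreements are logged as conflicts.

Records with no usable linking identifiers or out-of-period dates are
quarantined to an exceptions file, never silently dropped. The partition
invariant is: assigned records + quarantined + out-of-scope + unmatched
deaths = all input records, with no record in two persons.

## Case classification

The 5-year window is a rolling 1826-day span (5 × 365.25 rounded down),
inclusive at the boundary — the stricter, encounter-order-free reading; a
calendar-year reading would admit spans up to six years. "Separate
encounters" are distinct service dates after pooling Medicaid and hospital
records (duplicate billing of one event counts once); a date carrying both
trait and non-trait codes is an SCD encounter date. One deliberate extension:
any nonzero coded-encounter history that misses the probable tier classifies
POSSIBLE (not just the literal one-or-two-encounter reading). The literal
rule would send a person with two trait dates plus one later SCD date from
POSSIBLE to NONE, violating the upgrade-only direction that retention of
possible cases exists to serve; the extension makes classification provably
monotone in evidence. Trait-only histories therefore cap at POSSIBLE no
matter how many encounters. ICD system is accepted by the record's declared
system on any date (no hard cutover enforcement at the 2015 transition).

## Reports

A person counts in a source row iff ≥1 linked record of that source is dated
in-period; only confirmed and probable persons are reported; possible persons
stay in the index. Percent-of-total cells round half-up to one decimal (the
printed-table convention — banker's rounding would differ on exact halves).
Person-years count distinct calendar years with ≥1 in-period record in the
longitudinal source (a Medicaid claim with reported enrollment of zero months
is treated as a reporting artifact and does not qualify its year). The annual
report's migration adjustment counts a person in year Y iff not known dead
before Jan 1 of Y and having health-care evidence in Y or both before and
after Y; death handling is a conservative choice the source material leaves
open, and the unadjusted (in-year-evidence-only) mode is exposed by flag.
Strata: genotype percentages among confirmed persons with a known genotype;
the unknown-genotype column counts probable persons plus confirmed persons
without a genotype result; the pediatric stratum is age 0–18 inclusive at
mid-year (July 1), since no reference date is prescribed.

Truth-based evaluation restricts the denominator to persons with at least one
emitted record — persons invisible to every source are undiscoverable by any
design and would contaminate specificity with structural zeros. A person is
predicted positive when any of their records sits in an entry classified
confirmed or probable. Pairwise linkage precision/recall/F1 are computed from
cluster-size contingency counts over the records assigned to index persons.

## Problem sizes and numerical choices

The noiseless acceptance run uses a 5,000-person population at 2% prevalence
(~100 cases, ~15,000 records); the default-noise replicates use 2,000 persons
× 5 seeds, sizes at which binomial sampling error on the reported rates is a
few percent and a full run completes in seconds. All randomness flows from a
single integer seed through independent named substreams (truth vs.
emission), so identical config + seed reproduce byte-identical output files.
Weights and similarities are plain double arithmetic; the only rounding in
the reporting path is the final half-up percent formatting.

## Known limitations

Linkage parameters are hand-set, not estimated; no privacy-preserving or
machine-learned linkage; no cross-state federation; code sets cover SCD and
trait only (no procedure/NDC handling, no other hemoglobinopathies); the
possible tier's evaluation here reflects the generator's miscoding model, not
any real claims population.
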