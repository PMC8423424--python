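# Methods

## The problem being modelled

Code-list phenotyping algorithms define disease status by enumerating
terminology codes across linked EHR sources: primary-care diagnosis codes,
hospital discharge diagnoses, death-certificate causes, prescription codes
and laboratory fields. When such data are converted to a common data model,
two things can silently change the patient population an algorithm
identifies: *loss* (codes or rows that fail to map or are excluded) and
*gain* (several source codes collapsing onto one standard concept, so that
codes outside the original list become indistinguishable from codes inside
it). This package implements the conversion, the phenotyping and the
accounting that quantifies both effects, at a scale where every number can
be verified against planted ground truth.

## Transformation rules

**Observation period.** start = max(registration date, practice
up-to-standard date); end = min(transfer-out, practice last collection,
death, study end). An inverted period (start > end) or a missing
registration date rejects the patient; rejection is total — all of the
patient's rows in every source table are sent to the exclusion ledger with
reason `rejected-patient` (the patient row itself with
`inconsistent-observation-period`), and the person never appears in the
CDM. This makes a dangling person reference impossible by construction;
the quality module still checks for it. The study end date is
configurable, default 2016-03-08.

**Person.** Sex and year of birth come from primary care. Ethnicity comes
*exclusively* from hospital records, even when primary care holds a value;
patients never hospitalized therefore have null CDM ethnicity. This is a
deliberate asymmetry between representations (it mirrors how multi-source
conversions typically privilege one source per attribute), and it is why
the ethnicity comparison row in the evaluation report is the one
demographic row not expected to be identical in a defect-free round trip.

**Visits.** One visit per distinct (encounter id, patient id, date)
composite key per source. Surrogate integer ids are assigned in sorted
composite-key order, so ids are reproducible across runs. Encounters with
missing dates are excluded (`missing-date`). Hospital visit end dates are
set equal to the admission date: discharge dates are not modelled, and the
choice is recorded here rather than inferred.

**Event routing.** Each coded event resolves through the vocabulary store;
the target table is the resolved concept's domain. One-to-many resolutions
emit one row per target concept, all sharing a provenance pointer
(`source_table`, `source_row_id`) to the single source row, which keeps
conservation auditable. Unmapped codes produce one exclusion entry
(`unmapped-code`) and a mapping-ledger entry with a null target. An event
referencing an encounter absent from the consultation table keeps a null
visit reference and an `invalid_visit_flag`; an event whose encounter
exists but produced no visit (e.g. the encounter's own date is missing)
keeps a null reference without a flag — the two situations have different
causes and are kept distinguishable. Events dated outside the observation
period are retained and only surface in the quality report; dropping them
would hide exactly the class of inconsistency the profiling is meant to
expose.

**Prescriptions.** Drug codes resolve through a two-hop chain:
prescription code → drug-dictionary entry (`translates-to` edge) → standard
drug concept (`maps-to` edge from the dictionary entry's own code). Both
hops must exist; a broken second hop leaves the event unmapped. Exposures
are merged into eras per (person, concept): consecutive start dates at most
`era_gap_days` apart join one era, which ends at the last start plus
`drug_duration_days`. Both default to 30 days — community convention for
prescription data without explicit durations.

**Wide-format entity rows.** A test/additional row carries an entity type
and eight value slots. Each populated slot with a mapped
(entity type, field index) entry becomes one measurement; populated slots
without a usable mapping count as unmapped; slots with `ignore-zero`
semantics holding "0" (the "value not entered" convention) are excluded.
Empty slots count as nothing. Unit codes resolve through a unit map;
a missing unit mapping never drops the measurement — the value is kept
with a null unit concept.

**Conservation.** After every run the engine asserts, per source table:
rows in = source rows emitted (fan-out counted once per source row) +
exclusion-ledger entries, at field granularity for wide tables and
diagnosis/procedure slots. A violation raises; it cannot be silently
logged away.

## Phenotyping

A definition is (name, kind, sources, per-terminology code lists).
Translation takes the union of concept resolutions over all codes;
duplicates collapse — this is the step where a many-to-one vocabulary
shrinks a code list into fewer concepts and where phenotype broadening
originates. Execution against the raw bundle matches codes per source;
against the CDM it matches the translated concept set in the tables
appropriate to the phenotype kind, scanning the death table only when the
definition includes the mortality source (mirroring the source-side rule).

Incident-cohort rules: index = earliest event on/after 1998-01-01;
exclusions for age under 18 at index (age = index year − year of birth,
since only birth year exists) and for less than one year between
observation-period start and index. The one-year boundary is inclusive:
exactly 365 days qualifies. Rules are evaluated independently per patient,
so exclusion order cannot matter. Biomarker summaries use each patient's
first value on or after the index date within follow-up (median, IQR,
mean, SD over patients); medication flags are the percentage of the cohort
with at least one mapped exposure; smoking uses the last known status on
or before index, falling back to any known status.

## The synthetic study

The generator emulates a heart-failure study population in UK-style linked
EHR. Defaults are the study conditions: 2,000 patients, study window
1998-01-01 to 2016-03-08, HF prevalence 0.60 with comorbidity prevalences
(AF 0.354, COPD 0.4955, T2DM 0.2386, AMI 0.2029, HT 0.6584, cancer 0.2686)
and medication-class prevalences (loop diuretics 0.422, ACE inhibitors
0.502, beta blockers 0.483) matching the within-cohort frequencies such
studies report. Biomarkers are drawn from the corresponding clinical
distributions (SBP 143.07 ± 22.42 mmHg, DBP 80.05 ± 12.19, BMI
28.9 ± 6.44 kg/m², creatinine 102.76 ± 58.09 µmol/L, clipped at
physiological floors). Smoking status is 64.6 % smoker / 31.0 % never /
4.4 % ex. About 15 % of patients die under follow-up and 10 % transfer out;
the two are mutually exclusive so that, absent planted defects, no record
can fall outside its observation period. Each patient averages 20
consultations (source-table cardinalities are otherwise unconstrained by
the literature; one consultation per ~6 months of a ~10-year window was
chosen as realistic primary-care contact frequency).

Code systems are self-contained but structurally mirror real ones
(prefix + digits), with four codes per phenotype plus background pools
that stay disjoint from every phenotype list — which is what makes planted
membership exactly recoverable. The vocabulary is bijective on phenotype
codes by default; many-to-one collapse is introduced only by the explicit
injection operation, which adds codes resolving into a chosen phenotype's
concept set and emits them for known carriers, recording the expected
"incorrectly mapped" set (carriers minus true members) in the manifest.

**Defect model.** Five defect families, each applied by row-level
Bernoulli draws from a dedicated random stream, so changing one rate never
reshuffles another's rows. Default rates follow the magnitudes reported
for national linked EHR: missing encounter dates 0.0004, inverted
observation periods 0.0007, orphan prescription rows 0.19, unmappable
codes 0.025, zero-valued entity fields 0.12. Eligibility sets are
disjoint by construction: inverted-period patients are drawn first and
excluded from the other pools; missing dates target only consultations
without coded child rows (plus hospital spells); orphan rows target only
prescriptions whose drug code actually maps. These restrictions exist so
that each defect surfaces downstream under exactly one ledger reason and
the manifest count can be compared for equality, not approximately.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: disease natural history (codes are placed
uniformly within the observation window, so incidence has no age or
calendar trend), free text, dosing, realistic code-frequency skew within a
phenotype's list, regional/practice-level variation, and the real OMOP
vocabulary's scale and irregularities. Recovery results demonstrate the
*accounting* is exact, not that real-world coverage percentages transfer.

## Numerical choices

Reported percentages use exact decimal arithmetic and are **truncated**
(rounded toward zero) to the reported precision by default, with banker's
rounding available as an option. Truncation is the rule under which the
package's accounting reproduces the reference concordance table's printed
cells (22 of 24; the remaining two cells of one row are consistent only
with round-half-even — no single rule reproduces all 24, so the
better-fitting rule was adopted and the discrepancy is asserted honestly
in the acceptance suite rather than papered over). Concordance
denominators: source cohort size for the original column, CDM cohort size
for the CDM column, the phenotype's own source/CDM counts for the
unmapped/incorrectly-mapped columns — the combination verified to
reproduce the reference cells. Outside-period comparisons are inclusive of
boundary days. Tie-breaks: the largest-gap scan breaks ties
alphabetically; visit and person surrogate ids are assigned in sorted-key
order. Degenerate inputs (zero denominators, empty event sets, empty CDM)
return flagged zero-value results rather than raising.

## Determinism

Every random decision derives from `(seed, stream-index)` seed sequences
with fixed stream indices per purpose. Identical configuration and seed
produce byte-identical CSV bundles, manifests and reports; the test suite
asserts this at file level.

## Problem sizes

The test suite runs the end-to-end properties at 300 patients and the two
at-scale acceptance properties (round trip, defect recovery) at 2,000
patients — the size at which planted counts are large enough to make exact
recovery a meaningful check while a full generate→ETL→evaluate→profile
cycle stays under ~20 seconds. `scripts/acceptance.py` uses the same
2,000-patient configuration.

## Known limitations

- Hospital discharge dates, provider/care-site tables, cost tables and
  specimen/free-text tables are not modelled (the corresponding CDM tables
  are not populated).
- Prevalent vs incident HF is not distinguished in the comparison
  denominators: the cohort compared across representations is the full set
  of patients identified with the phenotype; incident-entry rules apply
  only to the covariate summaries.
- Real-data outside-period rates depend on the source's period formula and
  data vintage; the synthetic defaults produce near-zero outside-period
  counts by design, so those rates are not comparable to field reports.
- The ETL is single-shot: re-running onto an existing output directory is
  refused rather than merged.
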