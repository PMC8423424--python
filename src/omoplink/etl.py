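"""Source bundle -> CDM bundle transformation.

The transformation follows fixed rules:

- observation period: start = max(registration, practice up-to-standard),
  end = min(transfer-out, practice last collection, death, study end);
  a patient whose period is inverted (start after end) or who lacks a
  registration date is rejected outright and contributes zero rows to every
  CDM table — all their rows land in the exclusion ledger;
- person: demographics from primary care, ethnicity exclusively from
  hospital records (even when primary care disagrees);
- visits: one per distinct (encounter id, patient id, date) key per source;
  encounters without dates are excluded with reason ``missing-date``;
- events: each source event resolves through the vocabulary and is routed
  to the CDM table of the resolved concept's domain; one-to-many
  resolutions fan out into one row per target concept sharing a provenance
  pointer; unmapped codes go to the exclusion and mapping ledgers; an event
  referencing an encounter absent from the consultation table keeps a null
  visit reference and is flagged (``invalid_visit_flag``);
- events dated outside the observation period are retained (the quality
  module reports them); drug exposures are merged into eras using a start-
  to-start gap rule.

Every source row is conserved: it either becomes >= 1 CDM row or exactly
one ledger entry, and this accounting is asserted after every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import pandas as pd

from .errors import IntegrityError
from .io import CdmBundle, SourceBundle, coerce_frame, empty_frame
from .schemas import (CDM_SCHEMAS, N_DIAG_SLOTS, N_PROC_SLOTS,
                      N_SECONDARY_CAUSES)
from .vocab import VocabularyStore

logger = logging.getLogger("omoplink.etl")

#: resolved concept domain -> CDM target table
DOMAIN_TABLE = {
    "condition": "condition_occurrence",
    "procedure": "procedure_occurrence",
    "drug": "drug_exposure",
    "measurement": "measurement",
    "observation": "observation",
}


@dataclass
class EtlOptions:
    study_end: date = date(2016, 3, 8)
    era_gap_days: int = 30
    drug_duration_days: int = 30


@dataclass
class EtlResult:
    cdm: CdmBundle
    counts: dict[str, dict[str, int]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# observation periods and person assembly
# ---------------------------------------------------------------------------

def build_observation_periods(bundle: SourceBundle, study_end: date
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient observation window; inverted or unregistered -> rejection."""
    practice = bundle.practice.set_index("practice_id")
    study_end = pd.Timestamp(study_end)
    periods, rejections = [], []
    for p in bundle.patient.itertuples(index=False):
        prac = practice.loc[p.practice_id]
        if pd.isna(p.registration_date):
            rejections.append((p.patient_id, "inconsistent-observation-period"))
            continue
        start = max(p.registration_date, prac["up_to_standard_date"])
        ends = [d for d in (p.transfer_out_date, prac["last_collection_date"],
                            p.death_date, study_end) if pd.notna(d)]
        end = min(ends)
        if start > end:
            rejections.append((p.patient_id, "inconsistent-observation-period"))
            continue
        periods.append((p.patient_id, start, end))
    return (pd.DataFrame(periods, columns=["patient_id", "period_start", "period_end"]),
            pd.DataFrame(rejections, columns=["patient_id", "reason"]))


def build_person(bundle: SourceBundle, vocab: VocabularyStore | None = None
                 ) -> pd.DataFrame:
    """One person row per source patient.

    Sex and year of birth come from primary care; ethnicity exclusively from
    hospital records — a primary-care-only ethnicity yields null.
    """
    if bundle.patient["patient_id"].duplicated().any():
        raise IntegrityError("patient: duplicate patient_id")
    hosp_eth: dict[str, str] = {}
    if len(bundle.hospital):
        hosp = bundle.hospital.sort_values("spell_id")
        for r in hosp.itertuples(index=False):
            if pd.notna(r.ethnicity_code) and r.patient_id not in hosp_eth:
                hosp_eth[r.patient_id] = r.ethnicity_code
    quintile = {}
    if len(bundle.death):
        for r in bundle.death.itertuples(index=False):
            if pd.notna(r.deprivation_quintile):
                quintile[r.patient_id] = int(r.deprivation_quintile)
    rows = []
    for i, p in enumerate(bundle.patient.sort_values("patient_id")
                          .itertuples(index=False), start=1):
        eth_code = hosp_eth.get(p.patient_id)
        eth_concept = None
        if eth_code is not None and vocab is not None \
                and "ethnicity" in vocab.vocabularies:
            targets = vocab.resolve(eth_code, "ethnicity")
            eth_concept = targets[0] if targets else None
        rows.append({"person_id": str(i), "patient_source_id": p.patient_id,
                     "sex": p.sex, "year_of_birth": int(p.year_of_birth),
                     "ethnicity_concept_id": eth_concept,
                     "ethnicity_source_code": eth_code,
                     "deprivation_quintile": quintile.get(p.patient_id)})
    return coerce_frame(pd.DataFrame(rows), CDM_SCHEMAS["person"]) if rows \
        else empty_frame(CDM_SCHEMAS["person"])


# ---------------------------------------------------------------------------
# visits
# ---------------------------------------------------------------------------

def build_visits(bundle: SourceBundle, accepted: set[str], person_ids: dict[str, int]
                 ) -> tuple[pd.DataFrame, list, dict[str, int]]:
    """One visit per distinct (encounter, patient, date) key.

    Returns (visit frame, exclusions, encounter-id -> visit-id map). Visit
    ids are surrogate integers assigned in sorted composite-key order, so
    they are reproducible across runs.
    """
    exclusions = []
    keys = []  # (source, encounter_id, patient_id, date)
    for c in bundle.consultation.itertuples(index=False):
        if c.patient_id not in accepted:
            exclusions.append(("consultation", c.consultation_id, "rejected-patient"))
        elif pd.isna(c.event_date):
            exclusions.append(("consultation", c.consultation_id, "missing-date"))
        else:
            keys.append(("primary-care", c.consultation_id, c.patient_id, c.event_date))
    for h in bundle.hospital.itertuples(index=False):
        if h.patient_id not in accepted:
            exclusions.append(("hospital", h.spell_id, "rejected-patient"))
        elif pd.isna(h.admission_date):
            exclusions.append(("hospital", h.spell_id, "missing-date"))
        else:
            keys.append(("hospital", h.spell_id, h.patient_id, h.admission_date))
    keys.sort()
    rows, visit_map = [], {}
    for vid, (source, encounter, pid, when) in enumerate(keys, start=1):
        visit_map[encounter] = vid
        rows.append({"visit_occurrence_id": str(vid), "person_id": person_ids[pid],
                     "visit_start_date": when, "visit_end_date": when,
                     "visit_source": source, "visit_source_value": encounter})
    frame = coerce_frame(pd.DataFrame(rows), CDM_SCHEMAS["visit_occurrence"]) if rows \
        else empty_frame(CDM_SCHEMAS["visit_occurrence"])
    return frame, exclusions, visit_map


# ---------------------------------------------------------------------------
# drug eras
# ---------------------------------------------------------------------------

def derive_drug_eras(drug_exposure: pd.DataFrame, gap_days: int = 30,
                     duration_days: int = 30) -> pd.DataFrame:
    """Merge exposures into eras per (person, drug concept).

    Exposures sorted by start date are merged while consecutive starts are
    at most ``gap_days`` apart; an era runs from the first start to the last
    start plus the default prescription duration.
    """
    if not len(drug_exposure):
        return empty_frame(CDM_SCHEMAS["drug_era"])
    rows = []
    frame = drug_exposure.dropna(subset=["drug_exposure_start_date"])
    grouped = frame.sort_values("drug_exposure_start_date").groupby(
        ["person_id", "drug_concept_id"], sort=True)
    for (person_id, concept_id), group in grouped:
        starts = list(group["drug_exposure_start_date"])
        era_start, prev, count = starts[0], starts[0], 1
        for start in starts[1:]:
            if (start - prev).days <= gap_days:
                prev = start
                count += 1
            else:
                rows.append((person_id, concept_id, era_start,
                             prev + pd.Timedelta(days=duration_days), count))
                era_start, prev, count = start, start, 1
        rows.append((person_id, concept_id, era_start,
                     prev + pd.Timedelta(days=duration_days), count))
    frame = pd.DataFrame(rows, columns=["person_id", "drug_concept_id",
                                        "drug_era_start_date", "drug_era_end_date",
                                        "drug_exposure_count"])
    frame.insert(0, "era_id", [str(i) for i in range(1, len(frame) + 1)])
    return coerce_frame(frame, CDM_SCHEMAS["drug_era"])


# ---------------------------------------------------------------------------
# event routing
# ---------------------------------------------------------------------------

class _Router:
    def __init__(self, vocab, visit_map, consult_ids, person_ids):
        self.vocab = vocab
        self.visit_map = visit_map
        self.consult_ids = consult_ids
        self.person_ids = person_ids
        self.tables: dict[str, list] = {t: [] for t in DOMAIN_TABLE.values()}
        self.exclusions: list[tuple[str, str, str]] = []
        self.mapping_ledger: dict[tuple[str, str], list[int | None]] = {}
        self.counts: dict[str, dict[str, int]] = {}

    def bump(self, table: str, what: str, by: int = 1):
        self.counts.setdefault(table, {})[what] = \
            self.counts.setdefault(table, {}).get(what, 0) + by

    def visit_ref(self, consultation_id):
        """(visit id, source value, invalid flag) for an encounter reference."""
        if consultation_id is None or pd.isna(consultation_id):
            return None, None, 0
        vid = self.visit_map.get(consultation_id)
        if vid is not None:
            return vid, consultation_id, 0
        # reference to an encounter that is absent from the consultation
        # table entirely -> flagged; present but unvisited (e.g. undated) -> not
        flag = 0 if consultation_id in self.consult_ids else 1
        return None, consultation_id, flag

    def record_mapping(self, code, vocabulary, targets):
        self.mapping_ledger.setdefault(
            (code, vocabulary), list(targets) if targets else [None])

    def emit(self, table, pid, concept_id, when, visit, source_code,
             source_vocabulary, source_table, source_row_id, extra=None):
        vid, vsv, flag = visit
        row = {"row_id": None, "person_id": self.person_ids[pid],
               "visit_occurrence_id": vid, "visit_source_value": vsv,
               "invalid_visit_flag": flag, "source_code": source_code,
               "source_vocabulary": source_vocabulary,
               "source_table": source_table, "source_row_id": source_row_id}
        concept_col, date_col = {
            "condition_occurrence": ("condition_concept_id", "condition_start_date"),
            "procedure_occurrence": ("procedure_concept_id", "procedure_date"),
            "drug_exposure": ("drug_concept_id", "drug_exposure_start_date"),
            "measurement": ("measurement_concept_id", "measurement_date"),
            "observation": ("observation_concept_id", "observation_date"),
        }[table]
        row[concept_col] = concept_id
        row[date_col] = when
        if extra:
            row.update(extra)
        self.tables[table].append(row)

    def route_coded(self, pid, code, vocabulary, when, consultation_id,
                    source_table, source_row_id) -> bool:
        """Resolve and emit one coded event; False when unmapped."""
        targets = self.vocab.resolve(code, vocabulary)
        self.record_mapping(code, vocabulary, targets)
        if not targets:
            self.exclusions.append((source_table, source_row_id, "unmapped-code"))
            self.bump(source_table, "unmapped")
            return False
        visit = self.visit_ref(consultation_id)
        for concept_id in targets:
            domain = self.vocab.domain_of(concept_id) or "observation"
            self.emit(DOMAIN_TABLE[domain], pid, concept_id, when, visit,
                      code, vocabulary, source_table, source_row_id)
        self.bump(source_table, "emitted_rows", len(targets))
        self.bump(source_table, "mapped")
        return True


def route_events(bundle: SourceBundle, vocab: VocabularyStore,
                 visit_map: dict[str, int], accepted: set[str],
                 person_ids: dict[str, int],
                 options: EtlOptions) -> _Router:
    consult_ids = set(bundle.consultation["consultation_id"])
    router = _Router(vocab, visit_map, consult_ids, person_ids)

    # primary-care coded diagnoses/observations ------------------------------
    for r in bundle.clinical.itertuples(index=False):
        router.bump("clinical", "rows_in")
        if r.patient_id not in accepted:
            router.exclusions.append(("clinical", r.row_id, "rejected-patient"))
            continue
        if pd.isna(r.event_date):
            router.exclusions.append(("clinical", r.row_id, "missing-date"))
            continue
        router.route_coded(r.patient_id, r.code, "read", r.event_date,
                           r.consultation_id, "clinical", r.row_id)

    # prescriptions (two-hop chain) ------------------------------------------
    for r in bundle.therapy.itertuples(index=False):
        router.bump("therapy", "rows_in")
        if r.patient_id not in accepted:
            router.exclusions.append(("therapy", r.row_id, "rejected-patient"))
            continue
        if pd.isna(r.event_date):
            router.exclusions.append(("therapy", r.row_id, "missing-date"))
            continue
        target = vocab.resolve_drug(r.drug_code)
        router.record_mapping(r.drug_code, "gemscript", [target] if target else [])
        if target is None:
            router.exclusions.append(("therapy", r.row_id, "unmapped-code"))
            router.bump("therapy", "unmapped")
            continue
        visit = router.visit_ref(r.consultation_id)
        router.emit("drug_exposure", r.patient_id, target, r.event_date, visit,
                    r.drug_code, "gemscript", "therapy", r.row_id)
        router.bump("therapy", "emitted_rows")
        router.bump("therapy", "mapped")

    # wide-format entity rows -> measurements --------------------------------
    for table_name in ("test", "additional"):
        frame = bundle.tables[table_name]
        value_cols = [f"value_{i}" for i in range(1, 9)]
        for r in frame.itertuples(index=False):
            router.bump(table_name, "rows_in")
            values = [getattr(r, c) for c in value_cols]
            populated = sum(1 for v in values if pd.notna(v) and str(v) != "")
            if r.patient_id not in accepted:
                router.exclusions.append((table_name, r.row_id, "rejected-patient"))
                continue
            if pd.isna(r.event_date):
                router.exclusions.append((table_name, r.row_id, "missing-date"))
                continue
            router.bump(table_name, "fields_in", populated)
            unit = None if pd.isna(r.unit_code) else r.unit_code
            res = vocab.resolve_entity_row(int(r.entity_type_id), values, unit)
            for cand in res.candidates:
                try:
                    number = float(cand.value)
                except ValueError:
                    number = None
                router.emit(
                    "measurement", r.patient_id, cand.concept_id, r.event_date,
                    (None, None, 0), f"{int(r.entity_type_id)}:{cand.field_index}",
                    "entity", table_name, r.row_id,
                    extra={"value_as_number": number,
                           "unit_concept_id": cand.unit_concept_id,
                           "unit_source_code": cand.unit_code})
            for idx in res.unmapped_fields:
                router.exclusions.append(
                    (table_name, f"{r.row_id}:f{idx}", "unmapped-code"))
                router.record_mapping(f"{int(r.entity_type_id)}:{idx}", "entity", [])
            for idx in res.excluded_fields:
                router.exclusions.append(
                    (table_name, f"{r.row_id}:f{idx}", "zero-value-entity"))
            router.bump(table_name, "emitted_rows", len(res.candidates))
            router.bump(table_name, "unmapped", len(res.unmapped_fields))
            router.bump(table_name, "zero_excluded", len(res.excluded_fields))

    # hospital discharge diagnoses and procedures ----------------------------
    diag_cols = [(f"diag_{i}", "icd10", "hospital-diag") for i in range(1, N_DIAG_SLOTS + 1)]
    proc_cols = [(f"proc_{i}", "opcs4", "hospital-proc") for i in range(1, N_PROC_SLOTS + 1)]
    for r in bundle.hospital.itertuples(index=False):
        rejected = r.patient_id not in accepted
        undated = pd.isna(r.admission_date)
        for col, vocabulary, label in diag_cols + proc_cols:
            code = getattr(r, col)
            if pd.isna(code):
                continue
            router.bump(label, "rows_in")
            slot_id = f"{r.spell_id}:{col}"
            if rejected:
                router.exclusions.append((label, slot_id, "rejected-patient"))
                continue
            if undated:
                router.exclusions.append((label, slot_id, "missing-date"))
                continue
            router.route_coded(r.patient_id, code, vocabulary, r.admission_date,
                               r.spell_id, label, slot_id)

    # mortality register ------------------------------------------------------
    death_rows = []
    cause_cols = [("underlying_cause", 0)] + \
        [(f"cause_{i}", i) for i in range(2, N_SECONDARY_CAUSES + 2)]
    for r in bundle.death.itertuples(index=False):
        rejected = r.patient_id not in accepted
        any_mapped = False
        for col, seq in cause_cols:
            code = getattr(r, col)
            if pd.isna(code):
                continue
            router.bump("death", "rows_in")
            cause_id = f"{r.patient_id}:c{seq}"
            if rejected:
                router.exclusions.append(("death", cause_id, "rejected-patient"))
                continue
            targets = vocab.resolve(code, "icd10")
            router.record_mapping(code, "icd10", targets)
            if not targets:
                router.exclusions.append(("death", cause_id, "unmapped-code"))
                router.bump("death", "unmapped")
                continue
            for concept_id in targets:
                death_rows.append({
                    "row_id": None, "person_id": person_ids[r.patient_id],
                    "death_date": r.death_date, "cause_concept_id": concept_id,
                    "cause_seq": seq, "source_code": code,
                    "source_table": "death", "source_row_id": cause_id})
                any_mapped = True
            router.bump("death", "emitted_rows", len(targets))
            router.bump("death", "mapped")
        if not rejected and not any_mapped:
            # preserve the fact of death even when no cause code mapped
            death_rows.append({
                "row_id": None, "person_id": person_ids[r.patient_id],
                "death_date": r.death_date, "cause_concept_id": None,
                "cause_seq": 0, "source_code": None,
                "source_table": "death", "source_row_id": f"{r.patient_id}:date"})
    router.tables["death"] = death_rows
    return router


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def _finalize(rows: list, name: str) -> pd.DataFrame:
    schema = CDM_SCHEMAS[name]
    if not rows:
        return empty_frame(schema)
    frame = pd.DataFrame(rows)
    frame["row_id"] = [str(i) for i in range(1, len(frame) + 1)]
    for col in schema.column_names:
        if col not in frame.columns:
            frame[col] = None
    return coerce_frame(frame[schema.column_names], schema)


def run_etl(bundle: SourceBundle, vocab: VocabularyStore,
            options: EtlOptions | None = None) -> EtlResult:
    """Transform a source bundle into a CDM bundle with full provenance."""
    options = options or EtlOptions()
    bundle.validate()

    periods, rejections = build_observation_periods(bundle, options.study_end)
    accepted = set(periods["patient_id"])
    logger.info("stage=observation_period accepted=%d rejected=%d",
                len(accepted), len(rejections))

    person_all = build_person(bundle, vocab)
    person = person_all[person_all["patient_source_id"].isin(accepted)].reset_index(drop=True)
    person_ids = dict(zip(person["patient_source_id"],
                          person["person_id"].astype(str).map(int)))

    exclusions: list[tuple[str, str, str]] = []
    for r in rejections.itertuples(index=False):
        exclusions.append(("patient", r.patient_id, r.reason))

    period_rows = [{"person_id": str(person_ids[r.patient_id]),
                    "observation_period_start_date": r.period_start,
                    "observation_period_end_date": r.period_end}
                   for r in periods.itertuples(index=False)]
    period_frame = coerce_frame(pd.DataFrame(period_rows),
                                CDM_SCHEMAS["observation_period"]) if period_rows \
        else empty_frame(CDM_SCHEMAS["observation_period"])

    visits, visit_exclusions, visit_map = build_visits(bundle, accepted, person_ids)
    exclusions.extend(visit_exclusions)
    logger.info("stage=visits conservation consultations_in=%d hospital_in=%d "
                "visits=%d excluded=%d", len(bundle.consultation),
                len(bundle.hospital), len(visits), len(visit_exclusions))

    router = route_events(bundle, vocab, visit_map, accepted, person_ids, options)
    exclusions.extend(router.exclusions)

    tables = {name: _finalize(rows, name) for name, rows in router.tables.items()}
    drug_era = derive_drug_eras(tables["drug_exposure"], options.era_gap_days,
                                options.drug_duration_days)

    excl_frame = coerce_frame(
        pd.DataFrame([{"ledger_id": str(i), "source_table": t, "row_id": r,
                       "reason": reason}
                      for i, (t, r, reason) in enumerate(exclusions, start=1)]),
        CDM_SCHEMAS["exclusions"]) if exclusions else empty_frame(CDM_SCHEMAS["exclusions"])
    mapping_rows = [{"ledger_id": None, "source_code": code, "vocabulary": voc,
                     "target_concept_id": tgt}
                    for (code, voc), targets in sorted(router.mapping_ledger.items())
                    for tgt in targets]
    for i, row in enumerate(mapping_rows, start=1):
        row["ledger_id"] = str(i)
    map_frame = coerce_frame(pd.DataFrame(mapping_rows),
                             CDM_SCHEMAS["code_mappings"]) if mapping_rows \
        else empty_frame(CDM_SCHEMAS["code_mappings"])

    cdm = CdmBundle(person=person, observation_period=period_frame,
                    visit_occurrence=visits, drug_era=drug_era,
                    exclusions=excl_frame, code_mappings=map_frame,
                    condition_occurrence=tables["condition_occurrence"],
                    procedure_occurrence=tables["procedure_occurrence"],
                    drug_exposure=tables["drug_exposure"],
                    measurement=tables["measurement"],
                    observation=tables["observation"],
                    death=tables["death"])
    cdm.validate()
    _assert_conservation(bundle, cdm, router, visit_exclusions)
    return EtlResult(cdm, router.counts)


def _assert_conservation(bundle, cdm, router, visit_exclusions):
    """rows-in = CDM rows emitted (fan-out counted once per source row) + ledger."""
    excl = cdm.exclusions
    by_reason = excl.groupby(["source_table"]).size().to_dict()

    def excluded(table):
        return int((excl["source_table"] == table).sum())

    checks = []
    n_visits_pc = int((cdm.visit_occurrence["visit_source"] == "primary-care").sum())
    n_visits_h = int((cdm.visit_occurrence["visit_source"] == "hospital").sum())
    checks.append(("consultation", len(bundle.consultation),
                   n_visits_pc + excluded("consultation")))
    checks.append(("hospital", len(bundle.hospital),
                   n_visits_h + excluded("hospital")))

    emitted_sources: dict[str, set] = {}
    for name in ("condition_occurrence", "procedure_occurrence", "drug_exposure",
                 "measurement", "observation", "death"):
        frame = cdm.tables[name]
        for st, rid in zip(frame["source_table"], frame["source_row_id"]):
            emitted_sources.setdefault(st, set()).add(rid)

    for table in ("clinical", "therapy"):
        n_in = len(bundle.tables[table])
        n_emitted = len(emitted_sources.get(table, set()))
        checks.append((table, n_in, n_emitted + excluded(table)))

    for table in ("test", "additional"):
        c = router.counts.get(table, {})
        fields_in = c.get("fields_in", 0)
        checks.append((f"{table}-fields", fields_in,
                       c.get("emitted_rows", 0) + c.get("unmapped", 0)
                       + c.get("zero_excluded", 0)))

    for label in ("hospital-diag", "hospital-proc", "death"):
        c = router.counts.get(label, {})
        n_in = c.get("rows_in", 0)
        n_mapped = c.get("mapped", 0)
        checks.append((label, n_in,
                       n_mapped + c.get("unmapped", 0) + excluded(label)
                       - (0 if label != "death" else 0)))

    for name, left, right in checks:
        logger.info("conservation table=%s rows_in=%d accounted=%d", name, left, right)
        if left != right:
            raise IntegrityError(
                f"conservation violated for {name}: rows_in={left} accounted={right}")
    del by_reason
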