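"""Synthetic three-source EHR bundle with known ground truth.

The generator emulates a UK-style linked EHR study: a primary-care extract
(patients, practices, consultations, coded diagnoses, prescriptions and
wide-format laboratory/examination rows), a hospital-admissions extract
(spells with up to 20 discharge-diagnosis slots and procedure slots) and a
mortality register (underlying plus secondary causes and a deprivation
quintile). Code systems are self-contained but structurally mirror the real
ones: Read-like primary-care codes, ICD-like diagnosis codes, OPCS-like
procedure codes and a two-hop prescription chain
(prescription code -> drug dictionary -> standard drug concept).

Every configured data-quality defect is planted by an independent
Bernoulli stream per defect type, and every affected row id is recorded in
a ground-truth manifest, so downstream ETL ledgers and quality reports can
be checked for *exact* recovery.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, VocabularyLookupError
from .io import SourceBundle, coerce_frame, empty_frame
from .phenotype import PhenotypeDefinition
from .schemas import SOURCE_SCHEMAS
from .vocab import Concept, EntityField, VocabularyStore

DEFECT_NAMES = (
    "missing_event_date",
    "inverted_observation_period",
    "orphan_therapy_row",
    "unmappable_code",
    "zero_value_entity_row",
)

#: default planted prevalences: a heart-failure study population with its
#: typical comorbidity and medication frequencies
DEFAULT_PREVALENCES = {
    "hf": 0.60,
    "af": 0.354,
    "copd": 0.4955,
    "t2dm": 0.2386,
    "ami": 0.2029,
    "ht": 0.6584,
    "cancer": 0.2686,
    "loop_diuretics": 0.422,
    "ace_inhibitors": 0.502,
    "beta_blockers": 0.483,
}

#: defect rates mirroring the magnitudes seen in national linked EHR
DEFAULT_DEFECT_RATES = {
    "missing_event_date": 0.0004,
    "inverted_observation_period": 0.0007,
    "orphan_therapy_row": 0.19,
    "unmappable_code": 0.025,
    "zero_value_entity_row": 0.12,
}

_MED_CLASSES = ("loop_diuretics", "ace_inhibitors", "beta_blockers")
_SMOKING = (("smoker", 0.646), ("never", 0.310), ("ex", 0.044))

# entity types: (id, table, [(field_idx, semantics, biomarker-or-None)])
_ENTITY_LAYOUT = (
    (101, "test", [(1, "numeric", "sbp"), (2, "numeric", "dbp"),
                   (3, "coded", None)]),            # blood pressure
    (102, "additional", [(1, "numeric", "bmi"), (2, "coded", None)]),
    (103, "test", [(1, "numeric", "creatinine")]),
    (104, "test", [(1, "ignore-zero", "sample"), (2, "coded", None)]),
)
_BIOMARKER_DIST = {  # mean, sd, lower clip, unit code
    "sbp": (143.07, 22.42, 60.0, "U01"),
    "dbp": (80.05, 12.19, 30.0, "U01"),
    "bmi": (28.9, 6.44, 12.0, "U02"),
    "creatinine": (102.76, 58.09, 20.0, "U03"),
    "sample": None,
}


@dataclass
class GeneratorConfig:
    n_patients: int = 2000
    study_start: date = date(1998, 1, 1)
    study_end: date = date(2016, 3, 8)
    phenotype_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    codes_per_phenotype: int = 4
    defect_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEFECT_RATES))
    visits_per_patient_mean: float = 20.0
    seed: int = 0
    ethnicity_disagreement_rate: float = 0.005
    drug_chain_break_fraction: float = 0.375
    entity_unmapped_field_rate: float = 0.3

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients", "must be >= 1")
        if not self.study_start < self.study_end:
            raise ConfigurationError("study_start", "must precede study_end")
        if (self.study_end - self.study_start).days < 400:
            raise ConfigurationError("study_end", "study window must span >= 400 days")
        for name, p in self.phenotype_prevalences.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("phenotype_prevalences",
                                         f"{name} fraction {p} outside [0, 1]")
        unknown = set(self.defect_rates) - set(DEFECT_NAMES)
        if unknown:
            raise ConfigurationError("defect_rates", f"unknown defect(s) {sorted(unknown)}")
        for name in DEFECT_NAMES:
            r = self.defect_rates.get(name, 0.0)
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError("defect_rates", f"{name} rate {r} outside [0, 1]")
        if self.codes_per_phenotype < 1:
            raise ConfigurationError("codes_per_phenotype", "must be >= 1")
        if self.visits_per_patient_mean <= 0:
            raise ConfigurationError("visits_per_patient_mean", "must be positive")
        if not 0 <= self.seed < 2**31:
            raise ConfigurationError("seed", "must be in [0, 2**31)")
        for fname in ("ethnicity_disagreement_rate", "drug_chain_break_fraction",
                      "entity_unmapped_field_rate"):
            v = getattr(self, fname)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(fname, f"{v} outside [0, 1]")


@dataclass
class GroundTruthManifest:
    """Planted truth: phenotype membership, defect rows, expected mismaps."""

    membership: dict[str, list[str]] = field(default_factory=dict)
    true_prevalence: dict[str, float] = field(default_factory=dict)
    defects: dict[str, list[str]] = field(default_factory=dict)
    realized_rates: dict[str, dict] = field(default_factory=dict)
    incorrectly_mapped: dict[str, list[str]] = field(default_factory=dict)
    ethnicity_disagreements: list[str] = field(default_factory=list)

    def members(self, phenotype: str) -> set[str]:
        return set(self.membership.get(phenotype, []))

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def read(cls, path: str | Path) -> "GroundTruthManifest":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class World:
    """A fully wired synthetic study: data, truth, vocabulary, definitions."""

    bundle: SourceBundle
    manifest: GroundTruthManifest
    vocab: VocabularyStore
    definitions: dict[str, PhenotypeDefinition]


# ---------------------------------------------------------------------------
# vocabulary + phenotype catalogue
# ---------------------------------------------------------------------------

class _Catalogue:
    def __init__(self):
        self.read_codes: dict[str, list[str]] = {}    # phenotype -> codes
        self.icd_codes: dict[str, list[str]] = {}
        self.drug_codes: dict[str, list[str]] = {}
        self.noise_read: list[str] = []
        self.noise_icd: list[str] = []
        self.noise_opcs: list[str] = []
        self.noise_drug: list[str] = []               # complete chains
        self.broken_drug: list[str] = []              # first hop only
        self.unmappable_read: list[str] = []
        self.smoking_codes: dict[str, str] = {}       # status -> read code
        self.biomarker_fields: dict[str, list[str]] = {}  # name -> ["101:1", ...]
        self.sample_entity: tuple[int, str] = (104, "test")
        self.entity_tables: dict[int, str] = {}
        self.entity_fields: dict[int, list[tuple[int, str, str | None]]] = {}


def build_vocabulary(config: GeneratorConfig) -> tuple[VocabularyStore, _Catalogue]:
    """Deterministic synthetic vocabulary + phenotype code catalogue."""
    store = VocabularyStore()
    cat = _Catalogue()
    next_id = [1000]

    def new_concept(code: str, vocabulary: str, domain: str | None,
                    standard: bool = True) -> int:
        cid = next_id[0]
        next_id[0] += 1
        store.add_concept(Concept(cid, code, vocabulary, domain, standard))
        return cid

    condition_phenos = [p for p in config.phenotype_prevalences
                        if p not in _MED_CLASSES]
    k = config.codes_per_phenotype
    for pi, pheno in enumerate(condition_phenos):
        reads, icds = [], []
        for j in range(k):
            code = f"R{pi + 1:02d}{j:03d}"
            cid = new_concept(f"SCT-{pheno}-{j}", "snomed", "condition")
            store.add_edge(code, "read", cid)
            reads.append(code)
        for j in range(max(1, k // 2)):
            code = f"I{pi + 1:02d}{j:02d}"
            cid = new_concept(f"SCT-{pheno}-icd-{j}", "snomed", "condition")
            store.add_edge(code, "icd10", cid)
            icds.append(code)
        cat.read_codes[pheno] = reads
        cat.icd_codes[pheno] = icds

    for mi, med in enumerate(_MED_CLASSES):
        codes = []
        for j in range(k):
            gcode = f"G{mi + 1:02d}{j:03d}"
            dcode = f"D{mi + 1:02d}{j:03d}"
            dmd_id = new_concept(dcode, "dmd", "drug", standard=False)
            rx_id = new_concept(f"RX-{med}-{j}", "rxnorm", "drug")
            store.add_edge(gcode, "gemscript", dmd_id, relationship="translates-to")
            store.add_edge(dcode, "dmd", rx_id)
            codes.append(gcode)
        cat.drug_codes[med] = codes

    # background codes: all mapped; separate pools stay disjoint from the
    # phenotype code lists so planted membership is exactly recoverable
    for j in range(40):
        code = f"R90{j:03d}"
        cid = new_concept(f"SCT-noise-{j}", "snomed",
                          "observation" if j % 4 == 0 else "condition")
        store.add_edge(code, "read", cid)
        cat.noise_read.append(code)
    for j in range(20):
        code = f"I90{j:02d}"
        cid = new_concept(f"SCT-noise-icd-{j}", "snomed", "condition")
        store.add_edge(code, "icd10", cid)
        cat.noise_icd.append(code)
    for j in range(10):
        code = f"OP9{j:02d}"
        cid = new_concept(f"SCT-proc-{j}", "snomed", "procedure")
        store.add_edge(code, "opcs4", cid)
        cat.noise_opcs.append(code)

    n_drug_noise = 16
    n_broken = round(config.drug_chain_break_fraction * n_drug_noise)
    for j in range(n_drug_noise):
        gcode = f"G90{j:03d}"
        dcode = f"D90{j:03d}"
        dmd_id = new_concept(dcode, "dmd", "drug", standard=False)
        store.add_edge(gcode, "gemscript", dmd_id, relationship="translates-to")
        if j < n_drug_noise - n_broken:
            rx_id = new_concept(f"RX-noise-{j}", "rxnorm", "drug")
            store.add_edge(dcode, "dmd", rx_id)
            cat.noise_drug.append(gcode)
        else:
            cat.broken_drug.append(gcode)  # second hop missing

    for j in range(8):
        code = f"RU9{j:02d}"
        store.register_term("read", code)  # inventory term with no edge
        cat.unmappable_read.append(code)
    for j in range(30):  # terminology inventory never used in events
        store.register_term("read", f"RX8{j:03d}")
    for j in range(6):
        store.register_term("icd10", f"I98{j:02d}")
    for j in range(4):
        store.register_term("opcs4", f"OP98{j}")
    for j in range(6):
        store.register_term("gemscript", f"G98{j:03d}")

    for status, _ in _SMOKING:
        code = f"RS{status[:2].upper()}1"
        cid = new_concept(f"SCT-smoking-{status}", "snomed", "observation")
        store.add_edge(code, "read", cid)
        cat.smoking_codes[status] = code

    for eth in range(1, 6):
        code = f"ETH{eth}"
        cid = new_concept(f"ETHN-{eth}", "ethnicity-std", "observation")
        store.add_edge(code, "ethnicity", cid)

    for entity_id, table, fields in _ENTITY_LAYOUT:
        cat.entity_tables[entity_id] = table
        cat.entity_fields[entity_id] = list(fields)
        for idx, semantics, biomarker in fields:
            key = f"{entity_id}:{idx}"
            if biomarker is not None:
                cid = new_concept(f"LOINC-{biomarker}", "loinc", "measurement")
                store.entity_map[(entity_id, idx)] = EntityField(cid, semantics)
                store.add_edge(key, "entity", cid)
                cat.biomarker_fields.setdefault(biomarker, []).append(key)
            else:
                store.entity_map[(entity_id, idx)] = EntityField(None, semantics)
                store.register_term("entity", key)

    for j, code in enumerate(["U01", "U02", "U03"]):
        cid = new_concept(f"UCUM-{j}", "ucum", "unit")
        store.add_edge(code, "unit", cid)
        store.unit_map[code] = cid
    for code in ["U04", "U05", "U06", "U07"]:
        store.register_term("unit", code)  # units with no UCUM mapping
        store.unit_map[code] = None

    return store, cat


def build_definitions(config: GeneratorConfig, cat: _Catalogue
                      ) -> dict[str, PhenotypeDefinition]:
    defs: dict[str, PhenotypeDefinition] = {}
    for pheno in cat.read_codes:
        sources = ("primary-care", "hospital", "death") if pheno == "hf" \
            else ("primary-care", "hospital")
        defs[pheno] = PhenotypeDefinition(
            name=pheno, kind="condition", sources=sources,
            codelists={"read": list(cat.read_codes[pheno]),
                       "icd10": list(cat.icd_codes[pheno])})
    for med in cat.drug_codes:
        defs[med] = PhenotypeDefinition(
            name=med, kind="medication-class", sources=("primary-care",),
            codelists={"gemscript": list(cat.drug_codes[med])})
    for biomarker, keys in cat.biomarker_fields.items():
        if biomarker == "sample":
            continue
        defs[biomarker] = PhenotypeDefinition(
            name=biomarker, kind="biomarker", sources=("primary-care",),
            codelists={"entity": list(keys)})
    defs["smoking"] = PhenotypeDefinition(
        name="smoking", kind="lifestyle", sources=("primary-care",),
        codelists={"read": [cat.smoking_codes[s] for s, _ in _SMOKING]},
        categories={cat.smoking_codes[s]: s for s, _ in _SMOKING})
    return defs


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


_S_PRACTICE, _S_PATIENT, _S_MEMBER, _S_CONSULT, _S_EVENT, _S_NOISE, \
    _S_THERAPY, _S_ENTITY, _S_HOSPITAL, _S_DEATH, _S_SMOKING, _S_ETH = range(1, 13)
_S_DEFECT_BASE = 100


def _day(base: pd.Timestamp, offset: int) -> pd.Timestamp:
    return base + pd.Timedelta(days=int(offset))


def generate_world(config: GeneratorConfig) -> World:
    """Generate bundle + manifest + matching vocabulary and definitions."""
    config.validate()
    store, cat = build_vocabulary(config)
    defs = build_definitions(config, cat)

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    span = (end - start).days
    n = config.n_patients

    # practices ------------------------------------------------------------
    rng = _rng(config, _S_PRACTICE)
    n_prac = max(1, n // 250)
    practices = []
    for i in range(n_prac):
        uts = _day(start, rng.integers(0, max(1, int(span * 0.15))))
        last = _day(end, -int(rng.integers(0, max(1, int(span * 0.10)))))
        practices.append({"practice_id": f"PR{i:03d}",
                          "up_to_standard_date": uts, "last_collection_date": last})

    # patients ---------------------------------------------------------------
    rng = _rng(config, _S_PATIENT)
    patients = []
    windows = {}  # pid -> (window_start, window_end) both inside obs period
    for i in range(n):
        pid = f"P{i:06d}"
        prac = practices[int(rng.integers(0, n_prac))]
        sex = "F" if rng.random() < 0.524 else "M"
        yob = int(rng.integers(1920, 1991))
        reg = _day(start, rng.integers(0, max(1, int(span * 0.6))))
        w_start = max(reg, prac["up_to_standard_date"])
        base_end = min(prac["last_collection_date"], end)
        avail = (base_end - w_start).days
        transfer = death = None
        # transfer-out and death are mutually exclusive: a patient who dies
        # under follow-up is never also deregistered afterwards
        u_fate = rng.random()
        if u_fate < 0.15:
            death = _day(w_start, rng.integers(max(1, int(avail * 0.5)), avail + 1))
        elif u_fate < 0.25:
            transfer = _day(w_start, rng.integers(max(1, int(avail * 0.3)), avail + 1))
        w_end = min(d for d in (transfer, death, base_end) if d is not None)
        eth = f"ETH{1 if rng.random() < 0.91 else int(rng.integers(2, 6))}"
        pc_eth = eth if rng.random() < 0.7 else None
        patients.append({
            "patient_id": pid, "sex": sex, "year_of_birth": yob,
            "ethnicity_code": pc_eth, "registration_date": reg,
            "transfer_out_date": transfer, "practice_id": prac["practice_id"],
            "death_date": death, "_eth": eth,
        })
        windows[pid] = (w_start, w_end)

    def draw_day(r, pid):
        lo, hi = windows[pid]
        d = max(0, (hi - lo).days)
        return _day(lo, r.integers(0, d + 1))

    # phenotype membership ---------------------------------------------------
    rng = _rng(config, _S_MEMBER)
    membership: dict[str, list[str]] = {}
    for pheno in config.phenotype_prevalences:  # insertion order is fixed
        p = config.phenotype_prevalences[pheno]
        flags = rng.random(n) < p
        membership[pheno] = [patients[i]["patient_id"] for i in range(n) if flags[i]]
    rng = _rng(config, _S_SMOKING)
    statuses = [s for s, _ in _SMOKING]
    probs = np.array([w for _, w in _SMOKING])
    probs = probs / probs.sum()
    smoking_status = {p["patient_id"]: statuses[int(rng.choice(len(statuses), p=probs))]
                      for p in patients}

    # consultations ----------------------------------------------------------
    rng = _rng(config, _S_CONSULT)
    consults = []          # row dicts
    consult_of = {}        # pid -> list of consultation row indices
    for p in patients:
        pid = p["patient_id"]
        n_c = max(1, int(rng.poisson(config.visits_per_patient_mean)))
        consult_of[pid] = []
        for _ in range(n_c):
            idx = len(consults)
            consults.append({"consultation_id": f"C{idx:07d}", "patient_id": pid,
                             "event_date": draw_day(rng, pid)})
            consult_of[pid].append(idx)
    has_child = np.zeros(len(consults), dtype=bool)

    def attach(r, pid):
        idx = consult_of[pid][int(r.integers(0, len(consult_of[pid])))]
        has_child[idx] = True
        return consults[idx]["consultation_id"], consults[idx]["event_date"]

    clinical = []
    therapy = []
    hospital_queue: dict[str, list[str]] = {}  # pid -> icd codes for spells
    death_route_hf: set[str] = set()

    # condition events -------------------------------------------------------
    rng = _rng(config, _S_EVENT)
    member_sets = {ph: set(ids) for ph, ids in membership.items()}
    dead = {p["patient_id"]: p["death_date"] is not None for p in patients}
    for pheno in cat.read_codes:
        if pheno not in member_sets:
            continue
        reads, icds = cat.read_codes[pheno], cat.icd_codes[pheno]
        p_hosp = 0.25 if pheno == "hf" else 0.2
        for p in patients:
            pid = p["patient_id"]
            if pid not in member_sets[pheno]:
                continue
            emitted = False
            for ev in range(1 + int(rng.poisson(1.0))):
                u = rng.random()
                if pheno == "hf" and dead[pid] and u < 0.05:
                    # identified (also) through the mortality register
                    death_route_hf.add(pid)
                    emitted = True
                elif u < 1.0 - p_hosp:
                    cid, cdate = attach(rng, pid)
                    clinical.append({
                        "row_id": f"CL{len(clinical):07d}", "patient_id": pid,
                        "consultation_id": cid, "event_date": cdate,
                        "code": reads[int(rng.integers(0, len(reads)))]})
                    emitted = True
                else:
                    hospital_queue.setdefault(pid, []).append(
                        icds[int(rng.integers(0, len(icds)))])
                    emitted = True
            if not emitted:  # every planted member carries >= 1 code
                cid, cdate = attach(rng, pid)
                clinical.append({
                    "row_id": f"CL{len(clinical):07d}", "patient_id": pid,
                    "consultation_id": cid, "event_date": cdate,
                    "code": reads[0]})

    # background coded consultations ----------------------------------------
    rng = _rng(config, _S_NOISE)
    noise_row_ids = []
    for idx, c in enumerate(consults):
        if rng.random() < 0.6:
            has_child[idx] = True
            rid = f"CL{len(clinical):07d}"
            clinical.append({
                "row_id": rid, "patient_id": c["patient_id"],
                "consultation_id": c["consultation_id"], "event_date": c["event_date"],
                "code": cat.noise_read[int(rng.integers(0, len(cat.noise_read)))]})
            noise_row_ids.append(rid)

    # smoking observations ---------------------------------------------------
    rng = _rng(config, _S_SMOKING + 50)
    for p in patients:
        pid = p["patient_id"]
        for _ in range(1 + int(rng.integers(0, 2))):
            cid, cdate = attach(rng, pid)
            clinical.append({
                "row_id": f"CL{len(clinical):07d}", "patient_id": pid,
                "consultation_id": cid, "event_date": cdate,
                "code": cat.smoking_codes[smoking_status[pid]]})

    # prescriptions ----------------------------------------------------------
    rng = _rng(config, _S_THERAPY)
    for med in _MED_CLASSES:
        codes = cat.drug_codes[med]
        for pid in membership.get(med, []):
            for _ in range(1 + int(rng.poisson(4.0))):
                if rng.random() < 0.8:
                    cid, cdate = attach(rng, pid)
                else:
                    cid, cdate = None, draw_day(rng, pid)
                therapy.append({
                    "row_id": f"TH{len(therapy):07d}", "patient_id": pid,
                    "consultation_id": cid, "event_date": cdate,
                    "drug_code": codes[int(rng.integers(0, len(codes)))]})
    noise_pool = cat.noise_drug + cat.broken_drug
    for p in patients:
        pid = p["patient_id"]
        for _ in range(int(rng.poisson(2.0))):
            if rng.random() < 0.8:
                cid, cdate = attach(rng, pid)
            else:
                cid, cdate = None, draw_day(rng, pid)
            therapy.append({
                "row_id": f"TH{len(therapy):07d}", "patient_id": pid,
                "consultation_id": cid, "event_date": cdate,
                "drug_code": noise_pool[int(rng.integers(0, len(noise_pool)))]})

    # wide-format test/additional rows ---------------------------------------
    rng = _rng(config, _S_ENTITY)
    test_rows, additional_rows = [], []
    sample_row_ids = []

    def entity_row(pid, entity_id, values: dict[int, str], unit):
        table = cat.entity_tables[entity_id]
        rows = test_rows if table == "test" else additional_rows
        prefix = "TE" if table == "test" else "AD"
        row = {"row_id": f"{prefix}{len(rows):07d}", "patient_id": pid,
               "event_date": draw_day(rng, pid), "entity_type_id": entity_id,
               "unit_code": unit}
        for i in range(1, 9):
            row[f"value_{i}"] = values.get(i)
        rows.append(row)
        return row["row_id"]

    for p in patients:
        pid = p["patient_id"]
        for _ in range(int(rng.poisson(2.0))):  # blood pressure checks
            vals = {1: f"{max(60.0, rng.normal(143.07, 22.42)):.1f}",
                    2: f"{max(30.0, rng.normal(80.05, 12.19)):.1f}"}
            if rng.random() < config.entity_unmapped_field_rate:
                vals[3] = "5"  # korotkoff phase, no measurement mapping
            entity_row(pid, 101, vals, "U01")
        for _ in range(int(rng.poisson(1.5))):  # BMI
            vals = {1: f"{max(12.0, rng.normal(28.9, 6.44)):.1f}"}
            if rng.random() < config.entity_unmapped_field_rate:
                vals[2] = "N"
            entity_row(pid, 102, vals, "U02")
        for _ in range(int(rng.poisson(1.5))):  # creatinine
            unit = "U04" if rng.random() < 0.05 else "U03"
            entity_row(pid, 103,
                       {1: f"{max(20.0, rng.normal(102.76, 58.09)):.1f}"}, unit)
        for _ in range(int(rng.poisson(1.0))):  # specimen/sample bookkeeping
            vals = {1: "1"}
            if rng.random() < config.entity_unmapped_field_rate:
                vals[2] = "C"
            rid = entity_row(pid, 104, vals, None)
            sample_row_ids.append(rid)

    # hospital spells --------------------------------------------------------
    rng = _rng(config, _S_HOSPITAL)
    eth_rng = _rng(config, _S_ETH)
    hospital_rows = []
    eth_disagreements = []
    for p in patients:
        pid = p["patient_id"]
        queue = list(hospital_queue.get(pid, []))
        n_spells = int(rng.poisson(0.4))
        if queue:
            n_spells = max(1, n_spells)
        if n_spells == 0:
            continue
        hosp_eth = p["_eth"]
        if p["ethnicity_code"] is not None \
                and eth_rng.random() < config.ethnicity_disagreement_rate:
            others = [f"ETH{j}" for j in range(1, 6) if f"ETH{j}" != hosp_eth]
            hosp_eth = others[int(eth_rng.integers(0, len(others)))]
            eth_disagreements.append(pid)
        per_spell = [queue[i::n_spells] for i in range(n_spells)]
        for s in range(n_spells):
            diags = list(per_spell[s])
            for _ in range(1 + int(rng.integers(0, 3))):
                diags.append(cat.noise_icd[int(rng.integers(0, len(cat.noise_icd)))])
            diags = diags[:20]
            row = {"spell_id": f"H{len(hospital_rows):06d}", "patient_id": pid,
                   "admission_date": draw_day(rng, pid),
                   "ethnicity_code": hosp_eth}
            for i, code in enumerate(diags, start=1):
                row[f"diag_{i}"] = code
            if rng.random() < 0.3:
                row["proc_1"] = cat.noise_opcs[int(rng.integers(0, len(cat.noise_opcs)))]
            hospital_rows.append(row)

    # mortality register -----------------------------------------------------
    rng = _rng(config, _S_DEATH)
    death_rows = []
    for p in patients:
        if p["death_date"] is None:
            continue
        pid = p["patient_id"]
        if pid in death_route_hf:
            icds = cat.icd_codes["hf"]
            underlying = icds[int(rng.integers(0, len(icds)))]
        else:
            underlying = cat.noise_icd[int(rng.integers(0, len(cat.noise_icd)))]
        row = {"patient_id": pid, "death_date": p["death_date"],
               "underlying_cause": underlying,
               "deprivation_quintile": 5 if rng.random() < 0.15
               else int(rng.integers(1, 5))}
        for j in range(int(rng.integers(0, 4))):
            row[f"cause_{j + 2}"] = cat.noise_icd[int(rng.integers(0, len(cat.noise_icd)))]
        death_rows.append(row)

    # ---- planted defects ---------------------------------------------------
    manifest = GroundTruthManifest(
        membership={ph: sorted(ids) for ph, ids in membership.items()},
        true_prevalence={ph: len(ids) / n for ph, ids in membership.items()},
        ethnicity_disagreements=sorted(eth_disagreements),
    )

    def bernoulli(defect: str, eligible: list) -> list:
        rate = config.defect_rates.get(defect, 0.0)
        r = _rng(config, _S_DEFECT_BASE + DEFECT_NAMES.index(defect))
        hit = [e for e in eligible if r.random() < rate]
        manifest.realized_rates[defect] = {
            "affected": len(hit), "eligible": len(eligible),
            "rate": (len(hit) / len(eligible)) if eligible else 0.0}
        return hit

    # inverted periods are drawn first; the other defects only target rows of
    # intact patients, so each planted defect surfaces under its own ledger
    # reason and the per-defect lists stay disjoint
    hit_patients = bernoulli("inverted_observation_period", list(range(n)))
    inverted_ids = []
    prac_by_id = {pr["practice_id"]: pr for pr in practices}
    for i in hit_patients:
        p = patients[i]
        last = prac_by_id[p["practice_id"]]["last_collection_date"]
        p["registration_date"] = _day(last, 30 + (i % 300))
        inverted_ids.append(p["patient_id"])
    manifest.defects["inverted_observation_period"] = sorted(inverted_ids)
    inverted = set(inverted_ids)

    childless = [i for i in range(len(consults))
                 if not has_child[i] and consults[i]["patient_id"] not in inverted]
    intact_spells = [i for i in range(len(hospital_rows))
                     if hospital_rows[i]["patient_id"] not in inverted]
    hit_consults = bernoulli("missing_event_date",
                             [("consultation", i) for i in childless]
                             + [("hospital", i) for i in intact_spells])
    missing_ids = []
    for kind, i in hit_consults:
        if kind == "consultation":
            consults[i]["event_date"] = None
            missing_ids.append(consults[i]["consultation_id"])
        else:
            hospital_rows[i]["admission_date"] = None
            missing_ids.append(hospital_rows[i]["spell_id"])
    manifest.defects["missing_event_date"] = sorted(missing_ids)

    # only rows that will survive drug-code resolution are eligible, so the
    # planted count equals the dangling-visit flags observable downstream
    broken = set(cat.broken_drug)
    linked = [i for i, t in enumerate(therapy)
              if t["consultation_id"] is not None and t["drug_code"] not in broken
              and t["patient_id"] not in inverted]
    hit_therapy = bernoulli("orphan_therapy_row", linked)
    orphan_ids = []
    for j, i in enumerate(hit_therapy):
        therapy[i]["consultation_id"] = f"CX{j:06d}"  # no such consultation
        orphan_ids.append(therapy[i]["row_id"])
    manifest.defects["orphan_therapy_row"] = sorted(orphan_ids)

    noise_index = {r["row_id"]: r for r in clinical}
    hit_noise = bernoulli("unmappable_code",
                          [rid for rid in noise_row_ids
                           if noise_index[rid]["patient_id"] not in inverted])
    unmappable_ids = []
    for j, rid in enumerate(hit_noise):
        noise_index[rid]["code"] = cat.unmappable_read[j % len(cat.unmappable_read)]
        unmappable_ids.append(rid)
    manifest.defects["unmappable_code"] = sorted(unmappable_ids)

    sample_index = {r["row_id"]: r for r in test_rows}
    hit_samples = bernoulli("zero_value_entity_row",
                            [rid for rid in sample_row_ids
                             if sample_index[rid]["patient_id"] not in inverted])
    zero_ids = []
    for rid in hit_samples:
        sample_index[rid]["value_1"] = "0"  # "value not entered"
        zero_ids.append(rid)
    manifest.defects["zero_value_entity_row"] = sorted(zero_ids)

    # ---- assemble frames ---------------------------------------------------
    def frame(rows, name):
        schema = SOURCE_SCHEMAS[name]
        if not rows:
            return empty_frame(schema)
        df = pd.DataFrame(rows)
        for col in schema.column_names:
            if col not in df.columns:
                df[col] = None
        return coerce_frame(df[schema.column_names], schema)

    for p in patients:
        p.pop("_eth")
    bundle = SourceBundle(
        patient=frame(patients, "patient"),
        practice=frame(practices, "practice"),
        consultation=frame(consults, "consultation"),
        clinical=frame(clinical, "clinical"),
        therapy=frame(therapy, "therapy"),
        test=frame(test_rows, "test"),
        additional=frame(additional_rows, "additional"),
        hospital=frame(hospital_rows, "hospital"),
        death=frame(death_rows, "death"),
    )
    bundle.validate()
    return World(bundle, manifest, store, defs)


def generate(config: GeneratorConfig) -> tuple[SourceBundle, GroundTruthManifest]:
    """The spec'd entry point: bundle plus ground-truth manifest."""
    world = generate_world(config)
    return world.bundle, world.manifest


# ---------------------------------------------------------------------------
# many-to-one mapping injection
# ---------------------------------------------------------------------------

def inject_many_to_one_mapping(
    bundle: SourceBundle,
    vocab: VocabularyStore,
    manifest: GroundTruthManifest,
    phenotype: PhenotypeDefinition,
    n_codes: int = 2,
    n_carriers: int = 25,
    seed: int = 0,
    carriers: list[str] | None = None,
) -> tuple[SourceBundle, VocabularyStore, GroundTruthManifest]:
    """Plant the many-to-one code collapse that inflates CDM phenotype counts.

    Adds *n_codes* new primary-care codes that all map to a concept already
    inside *phenotype*'s concept set (so the codes are NOT in the phenotype's
    source code list, but their CDM translation is), and emits one such code
    for each carrier patient. Carriers default to a random sample of known
    non-members; an explicit ``carriers`` list may include true members, in
    which case only the non-members are expected to surface as incorrectly
    mapped. The expected set (carriers minus members) is recorded in the
    manifest.
    """
    read_list = phenotype.codelists.get("read", [])
    targets = [t for code in read_list for t in vocab.resolve(code, "read")]
    if not targets:
        raise VocabularyLookupError(
            f"phenotype {phenotype.name!r} has no mapped primary-care codes")
    target = targets[0]

    vocab = copy.deepcopy(vocab)
    new_codes = []
    for j in range(n_codes):
        code = f"RM2O{j:03d}"
        vocab.add_edge(code, "read", target)
        new_codes.append(code)

    members = manifest.members(phenotype.name)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 999]))
    if carriers is None:
        inverted = set(manifest.defects.get("inverted_observation_period", []))
        pool = sorted(set(bundle.patient["patient_id"]) - members - inverted)
        if n_carriers > len(pool):
            raise VocabularyLookupError(
                f"cannot place {n_carriers} carriers: only {len(pool)} eligible")
        carriers = [pool[i] for i in sorted(
            rng.choice(len(pool), size=n_carriers, replace=False).tolist())]
    else:
        carriers = list(carriers)

    # one carrier row each, dated mid-window so it lands inside the
    # observation period and cannot disturb quality counts
    patient = bundle.patient.set_index("patient_id")
    practice = bundle.practice.set_index("practice_id")
    clinical = bundle.clinical.copy()
    rows = []
    for i, pid in enumerate(carriers):
        p = patient.loc[pid]
        prac = practice.loc[p["practice_id"]]
        w_start = max(p["registration_date"], prac["up_to_standard_date"])
        w_end = min(d for d in (p["transfer_out_date"], p["death_date"],
                                prac["last_collection_date"]) if pd.notna(d))
        mid = w_start + (w_end - w_start) / 2
        rows.append({
            "row_id": f"CLM2O{i:05d}", "patient_id": pid,
            "consultation_id": None, "event_date": mid.normalize(),
            "code": new_codes[i % len(new_codes)]})
    if rows:
        add = coerce_frame(pd.DataFrame(rows)[clinical.columns.tolist()],
                           SOURCE_SCHEMAS["clinical"])
        clinical = pd.concat([clinical, add], ignore_index=True)

    new_bundle = SourceBundle(**{**bundle.tables, "clinical": clinical})
    new_manifest = copy.deepcopy(manifest)
    expected = sorted(set(carriers) - members)
    new_manifest.incorrectly_mapped[phenotype.name] = expected
    return new_bundle, vocab, new_manifest
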