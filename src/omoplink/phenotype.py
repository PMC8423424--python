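"""Code-list phenotyping executable against the raw bundle and the CDM.

A phenotype is a named set of per-terminology code lists plus the sources
it draws on (primary care, hospital, mortality). The same definition runs
against either representation: against the raw tables it matches source
codes directly; against the CDM it matches the translated concept set.
The translation step is where many-to-one code->concept collapse shrinks
(and can broaden) code lists, which is the mechanism behind
"incorrectly mapped" patients in the concordance report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import CdmBundle, SourceBundle
from .rounding import pct
from .schemas import N_DIAG_SLOTS, N_PROC_SLOTS, N_SECONDARY_CAUSES
from .vocab import VocabularyStore

KINDS = ("condition", "medication-class", "biomarker", "lifestyle")
SOURCES = ("primary-care", "hospital", "death")


@dataclass
class PhenotypeDefinition:
    name: str
    kind: str
    sources: tuple[str, ...]
    codelists: dict[str, list[str]]
    categories: dict[str, str] = field(default_factory=dict)  # code -> label
    concept_set: set[int] | None = None
    unmapped_codes: list[str] = field(default_factory=list)
    concept_categories: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ConfigurationError("kind", f"{self.kind!r} not one of {KINDS}")
        bad = set(self.sources) - set(SOURCES)
        if bad:
            raise ConfigurationError("sources", f"unknown source(s) {sorted(bad)}")
        if not any(self.codelists.values()):
            raise ConfigurationError("codelists", f"{self.name}: no non-empty code list")


@dataclass
class CohortRules:
    """Incident-cohort entry rules."""

    entry_start: date = date(1998, 1, 1)
    min_age: int = 18
    min_prior_days: int = 365  # inclusive: exactly one year of prior registration qualifies

    def __post_init__(self):
        if self.min_age <= 0 or self.min_prior_days <= 0:
            raise ConfigurationError("rules", "thresholds must be positive")


@dataclass
class PhenotypeResult:
    """Patients matching a phenotype in one representation.

    ``patients`` maps patient id -> earliest dated event (NaT-free; None when
    the patient matched only through undated rows). ``dates`` holds every
    dated event; ``records`` holds (date, value) pairs for biomarkers and
    (date, category) pairs for lifestyle phenotypes.
    """

    name: str
    patients: dict[str, pd.Timestamp | None] = field(default_factory=dict)
    dates: dict[str, list[pd.Timestamp]] = field(default_factory=dict)
    records: dict[str, list[tuple]] = field(default_factory=dict)

    @property
    def patient_ids(self) -> set[str]:
        return set(self.patients)

    def _add(self, pid: str, when, value=None) -> None:
        when = None if pd.isna(when) else pd.Timestamp(when)
        if pid not in self.patients:
            self.patients[pid] = when
        elif when is not None and (self.patients[pid] is None or when < self.patients[pid]):
            self.patients[pid] = when
        if when is not None:
            self.dates.setdefault(pid, []).append(when)
        if value is not None:
            self.records.setdefault(pid, []).append((when, value))

    def finish(self) -> "PhenotypeResult":
        for pid in self.dates:
            self.dates[pid].sort()
        for pid in self.records:
            self.records[pid].sort(key=lambda t: (t[0] is None, t[0]))
        return self


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def translate_codelist(defn: PhenotypeDefinition, vocab: VocabularyStore
                       ) -> tuple[set[int], list[str]]:
    """Union of concept resolutions over all of the phenotype's code lists.

    Duplicate targets collapse (a 2217-term list can land on far fewer
    concepts); codes without any resolution are reported back. The result is
    cached on the definition.
    """
    concepts: set[int] = set()
    unmapped: list[str] = []
    for terminology, codes in defn.codelists.items():
        for code in codes:
            if terminology == "gemscript":
                target = vocab.resolve_drug(code)
                targets = [] if target is None else [target]
            elif terminology == "entity":
                entity_id, idx = code.split(":")
                entry = vocab.entity_map.get((int(entity_id), int(idx)))
                targets = [] if entry is None or entry.target_concept_id is None \
                    else [entry.target_concept_id]
            else:
                targets = vocab.resolve(code, terminology)
            if targets:
                concepts.update(targets)
                if code in defn.categories:
                    for t in targets:
                        defn.concept_categories[t] = defn.categories[code]
            else:
                unmapped.append(code)
    defn.concept_set = concepts
    defn.unmapped_codes = unmapped
    return concepts, unmapped


# ---------------------------------------------------------------------------
# execution against the raw bundle
# ---------------------------------------------------------------------------

def _match_codes(result, frame, code_col, date_col, codes, categories=None):
    if not codes or not len(frame):
        return
    hit = frame[frame[code_col].isin(codes)]
    for r in hit.itertuples(index=False):
        value = categories.get(getattr(r, code_col)) if categories else None
        result._add(r.patient_id, getattr(r, date_col), value)


def find_patients_source(defn: PhenotypeDefinition, bundle: SourceBundle
                         ) -> PhenotypeResult:
    """Union across the phenotype's sources of patients carrying >= 1 code."""
    result = PhenotypeResult(defn.name)
    cats = defn.categories or None
    if "primary-care" in defn.sources:
        _match_codes(result, bundle.clinical, "code", "event_date",
                     set(defn.codelists.get("read", [])), cats)
        _match_codes(result, bundle.therapy, "drug_code", "event_date",
                     set(defn.codelists.get("gemscript", [])))
        entity_keys = defn.codelists.get("entity", [])
        if entity_keys:
            wanted = {}
            for key in entity_keys:
                ent, idx = key.split(":")
                wanted.setdefault(int(ent), []).append(int(idx))
            for frame in (bundle.test, bundle.additional):
                if not len(frame):
                    continue
                sub = frame[frame["entity_type_id"].isin(wanted)]
                for r in sub.itertuples(index=False):
                    for idx in wanted[int(r.entity_type_id)]:
                        raw = getattr(r, f"value_{idx}")
                        if pd.isna(raw):
                            continue
                        try:
                            value = float(raw)
                        except ValueError:
                            continue
                        result._add(r.patient_id, r.event_date, value)
    if "hospital" in defn.sources and len(bundle.hospital):
        icd = set(defn.codelists.get("icd10", []))
        opcs = set(defn.codelists.get("opcs4", []))
        for slot_codes, cols in (
                (icd, [f"diag_{i}" for i in range(1, N_DIAG_SLOTS + 1)]),
                (opcs, [f"proc_{i}" for i in range(1, N_PROC_SLOTS + 1)])):
            if not slot_codes:
                continue
            for col in cols:
                hit = bundle.hospital[bundle.hospital[col].isin(slot_codes)]
                for r in hit.itertuples(index=False):
                    result._add(r.patient_id, r.admission_date)
    if "death" in defn.sources and len(bundle.death):
        icd = set(defn.codelists.get("icd10", []))
        cause_cols = ["underlying_cause"] + \
            [f"cause_{i}" for i in range(2, N_SECONDARY_CAUSES + 2)]
        if icd:
            for col in cause_cols:
                hit = bundle.death[bundle.death[col].isin(icd)]
                for r in hit.itertuples(index=False):
                    result._add(r.patient_id, r.death_date)
    return result.finish()


# ---------------------------------------------------------------------------
# execution against the CDM
# ---------------------------------------------------------------------------

_KIND_TABLES = {
    "condition": ("condition_occurrence", "procedure_occurrence", "observation"),
    "medication-class": ("drug_exposure",),
    "biomarker": ("measurement",),
    "lifestyle": ("observation", "condition_occurrence"),
}
_CONCEPT_COL = {
    "condition_occurrence": ("condition_concept_id", "condition_start_date"),
    "procedure_occurrence": ("procedure_concept_id", "procedure_date"),
    "drug_exposure": ("drug_concept_id", "drug_exposure_start_date"),
    "measurement": ("measurement_concept_id", "measurement_date"),
    "observation": ("observation_concept_id", "observation_date"),
}


def find_patients_cdm(defn: PhenotypeDefinition, cdm: CdmBundle) -> PhenotypeResult:
    """Patients with >= 1 CDM event whose concept is in the translated set."""
    if defn.concept_set is None:
        raise ConfigurationError(
            "concept_set", f"phenotype {defn.name!r} has not been translated")
    result = PhenotypeResult(defn.name)
    person = cdm.person
    source_id = dict(zip(person["person_id"].astype(str).map(int),
                         person["patient_source_id"]))
    concepts = sorted(defn.concept_set)
    for table in _KIND_TABLES[defn.kind]:
        frame = cdm.tables[table]
        if not len(frame):
            continue
        concept_col, date_col = _CONCEPT_COL[table]
        hit = frame[frame[concept_col].isin(concepts)]
        for r in hit.itertuples(index=False):
            pid = source_id.get(int(r.person_id))
            if pid is None:
                continue
            if defn.kind == "biomarker":
                value = r.value_as_number
                value = None if pd.isna(value) else float(value)
            elif defn.kind == "lifestyle":
                value = defn.concept_categories.get(int(getattr(r, concept_col)))
            else:
                value = None
            result._add(pid, getattr(r, date_col), value)
    if "death" in defn.sources and len(cdm.death):
        hit = cdm.death[cdm.death["cause_concept_id"].isin(concepts)]
        for r in hit.itertuples(index=False):
            pid = source_id.get(int(r.person_id))
            if pid is not None:
                result._add(pid, r.death_date)
    return result.finish()


# ---------------------------------------------------------------------------
# demographics views and the incident cohort
# ---------------------------------------------------------------------------

def demographics_from_source(bundle: SourceBundle, study_end: date) -> pd.DataFrame:
    """Per-patient year of birth and observation window, raw-table route."""
    practice = bundle.practice.set_index("practice_id")
    rows = []
    for p in bundle.patient.itertuples(index=False):
        prac = practice.loc[p.practice_id]
        start = max(p.registration_date, prac["up_to_standard_date"])
        ends = [d for d in (p.transfer_out_date, prac["last_collection_date"],
                            p.death_date, pd.Timestamp(study_end)) if pd.notna(d)]
        rows.append((p.patient_id, int(p.year_of_birth), start, min(ends)))
    return pd.DataFrame(rows, columns=["patient_id", "year_of_birth",
                                       "period_start", "period_end"]
                        ).set_index("patient_id")


def demographics_from_cdm(cdm: CdmBundle) -> pd.DataFrame:
    person = cdm.person.set_index("person_id")
    period = cdm.observation_period.set_index("person_id")
    rows = []
    for person_id, p in person.iterrows():
        if person_id not in period.index:
            continue
        op = period.loc[person_id]
        rows.append((p["patient_source_id"], int(p["year_of_birth"]),
                     op["observation_period_start_date"],
                     op["observation_period_end_date"]))
    return pd.DataFrame(rows, columns=["patient_id", "year_of_birth",
                                       "period_start", "period_end"]
                        ).set_index("patient_id")


def build_hf_cohort(result: PhenotypeResult, demographics: pd.DataFrame,
                    rules: CohortRules | None = None) -> pd.DataFrame:
    """Apply incident-cohort entry rules to a phenotype result.

    Index date is the earliest event on/after the entry start. Exclusions:
    no qualifying index event, no observation period, age at index under the
    minimum, or less than the minimum prior registration (inclusive
    boundary: exactly ``min_prior_days`` qualifies). Follow-up ends at the
    observation-period end. Exclusion order does not matter: each patient's
    rules are evaluated independently and the first failing reason (in the
    fixed order above) is recorded.
    """
    rules = rules or CohortRules()
    entry = pd.Timestamp(rules.entry_start)
    rows = []
    for pid in sorted(result.patients):
        dates = [d for d in result.dates.get(pid, []) if d >= entry]
        index_date = dates[0] if dates else None
        if index_date is None:
            rows.append((pid, None, None, False, "no-index-event"))
            continue
        if pid not in demographics.index:
            rows.append((pid, index_date, None, False, "no-observation-period"))
            continue
        demo = demographics.loc[pid]
        age = index_date.year - int(demo["year_of_birth"])
        if age < rules.min_age:
            rows.append((pid, index_date, None, False, "under-age"))
            continue
        if (index_date - demo["period_start"]).days < rules.min_prior_days:
            rows.append((pid, index_date, None, False, "insufficient-prior-registration"))
            continue
        rows.append((pid, index_date, demo["period_end"], True, "included"))
    return pd.DataFrame(rows, columns=["patient_id", "index_date",
                                       "follow_up_end", "included", "reason"])


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerSummary:
    n: int
    median: float | None
    iqr: float | None
    mean: float | None
    sd: float | None

    def as_tuple(self):
        return (self.n, self.median, self.iqr, self.mean, self.sd)


def summarize_biomarker(result: PhenotypeResult, cohort: pd.DataFrame
                        ) -> BiomarkerSummary:
    """Median/IQR/mean/SD of each cohort patient's first value on/after index."""
    included = cohort[cohort["included"]]
    values = []
    for r in included.itertuples(index=False):
        for when, value in result.records.get(r.patient_id, []):
            if when is None or value is None:
                continue
            if when >= r.index_date and (pd.isna(r.follow_up_end)
                                         or when <= r.follow_up_end):
                values.append(value)
                break
    if not values:
        return BiomarkerSummary(0, None, None, None, None)
    arr = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(arr, [75, 25])
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    return BiomarkerSummary(len(arr), float(np.median(arr)), float(q75 - q25),
                            float(arr.mean()), sd)


def medication_flag(result: PhenotypeResult, cohort: pd.DataFrame) -> float:
    """% of the cohort with >= 1 exposure in the class, one decimal."""
    included = set(cohort.loc[cohort["included"], "patient_id"])
    if not included:
        return 0.0
    exposed = len(included & result.patient_ids)
    return pct(exposed, len(included), places=1)


def smoking_summary(result: PhenotypeResult, cohort: pd.DataFrame
                    ) -> dict[str, tuple[int, float]]:
    """Last-known-status-before-index counts and percentages per category."""
    included = cohort[cohort["included"]]
    counts: dict[str, int] = {}
    for r in included.itertuples(index=False):
        status = None
        for when, category in result.records.get(r.patient_id, []):
            if when is not None and when <= r.index_date:
                status = category
        if status is None:  # fall back to any known status
            recs = result.records.get(r.patient_id, [])
            status = recs[0][1] if recs else None
        if status is not None:
            counts[status] = counts.get(status, 0) + 1
    denom = len(included)
    return {s: (c, pct(c, denom, places=2)) for s, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# definition files
# ---------------------------------------------------------------------------

def write_definition(defn: PhenotypeDefinition, path: str | Path) -> None:
    lines = [f"name: {defn.name}", f"kind: {defn.kind}",
             f"sources: {','.join(defn.sources)}"]
    for terminology in sorted(defn.codelists):
        codes = defn.codelists[terminology]
        if codes:
            lines.append(f"codes[{terminology}]: {','.join(codes)}")
    for code in sorted(defn.categories):
        lines.append(f"category[{code}]: {defn.categories[code]}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_definition(path: str | Path) -> PhenotypeDefinition:
    fields: dict = {"codelists": {}, "categories": {}}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        key, value = key.strip(), value.strip()
        if key == "name":
            fields["name"] = value
        elif key == "kind":
            fields["kind"] = value
        elif key == "sources":
            fields["sources"] = tuple(s.strip() for s in value.split(",") if s.strip())
        elif key.startswith("codes[") and key.endswith("]"):
            fields["codelists"][key[6:-1]] = \
                [c.strip() for c in value.split(",") if c.strip()]
        elif key.startswith("category[") and key.endswith("]"):
            fields["categories"][key[9:-1]] = value
        else:
            raise ConfigurationError("definition", f"unrecognized line {line!r}")
    return PhenotypeDefinition(**fields)


def write_definitions(defs: dict[str, PhenotypeDefinition], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, defn in sorted(defs.items()):
        write_definition(defn, directory / f"{name}.pheno")


def load_definitions(directory: str | Path) -> dict[str, PhenotypeDefinition]:
    defs = {}
    for path in sorted(Path(directory).glob("*.pheno")):
        defn = read_definition(path)
        defs[defn.name] = defn
    return defs
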