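"""Raw-vs-CDM comparison: coverage, cohort summary and concordance accounting.

The concordance accounting treats the two representations as patient sets:

- unmapped patients   = identified in the source but not in the CDM
                        (typically lost to unmapped codes or rejection);
- incorrectly mapped  = identified in the CDM but not in the source
                        (typically gained through many-to-one code->concept
                        collapse that pulls in codes outside the original
                        code list);

so that ``cdm_n = original_n - unmapped_n + incorrect_n`` holds identically.
Percentages: the original count over the original cohort size, the CDM count
over the CDM cohort size, unmapped over the original phenotype count and
incorrectly mapped over the CDM phenotype count — the denominators under
which the accounting reproduces reference tables. Reported percentages are
truncated to the printed precision by default (see ``rounding``).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import phenotype as ph
from .errors import ConfigurationError
from .io import CdmBundle, SourceBundle
from .rounding import pct
from .schemas import N_DIAG_SLOTS, N_PROC_SLOTS, N_SECONDARY_CAUSES
from .vocab import CoverageRow, VocabularyStore


@dataclass
class ConcordanceRow:
    phenotype: str
    original_n: int
    original_pct: float
    cdm_n: int
    cdm_pct: float
    unmapped_n: int
    unmapped_pct: float
    incorrect_n: int
    incorrect_pct: float
    degenerate: bool = False

    def __post_init__(self):
        if self.cdm_n != self.original_n - self.unmapped_n + self.incorrect_n:
            raise ConfigurationError(
                "concordance",
                f"{self.phenotype}: accounting identity violated "
                f"({self.cdm_n} != {self.original_n} - {self.unmapped_n} "
                f"+ {self.incorrect_n})")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def concordance(name: str, source_ids: set[str], cdm_ids: set[str],
                original_denominator: int, cdm_denominator: int,
                places: int = 2, unmapped_places: int = 2,
                incorrect_places: int = 2, mode: str = "truncate"
                ) -> ConcordanceRow:
    """Set-difference concordance accounting between the two representations."""
    source_ids, cdm_ids = set(source_ids), set(cdm_ids)
    unmapped = source_ids - cdm_ids
    incorrect = cdm_ids - source_ids
    o, c, u, i = len(source_ids), len(cdm_ids), len(unmapped), len(incorrect)
    if original_denominator <= 0 or cdm_denominator <= 0:
        return ConcordanceRow(name, o, 0.0, c, 0.0, u, 0.0, i, 0.0, degenerate=True)
    return ConcordanceRow(
        name,
        o, pct(o, original_denominator, places, mode),
        c, pct(c, cdm_denominator, places, mode),
        u, pct(u, o, unmapped_places, mode) if o else 0.0,
        i, pct(i, c, incorrect_places, mode) if c else 0.0,
    )


def concordance_from_counts(name: str, original_n: int, unmapped_n: int,
                            incorrect_n: int, original_denominator: int,
                            cdm_denominator: int, places: int = 2,
                            unmapped_places: int = 2, incorrect_places: int = 2,
                            mode: str = "truncate") -> ConcordanceRow:
    """Rebuild a row from printed (n, unmapped, incorrect); cdm_n follows."""
    cdm_n = original_n - unmapped_n + incorrect_n
    return ConcordanceRow(
        name,
        original_n, pct(original_n, original_denominator, places, mode),
        cdm_n, pct(cdm_n, cdm_denominator, places, mode),
        unmapped_n,
        pct(unmapped_n, original_n, unmapped_places, mode) if original_n else 0.0,
        incorrect_n,
        pct(incorrect_n, cdm_n, incorrect_places, mode) if cdm_n else 0.0,
    )


def prevalence_pct(count: int, denominator: int, places: int = 2,
                   mode: str = "truncate") -> float:
    if denominator <= 0:
        raise ConfigurationError("denominator", "prevalence with non-positive denominator")
    return pct(count, denominator, places, mode)


def max_prevalence_gap(rows: list[ConcordanceRow]) -> tuple[float, str]:
    """Largest |CDM% - original%| over rows; ties broken alphabetically."""
    if not rows:
        raise ConfigurationError("rows", "no concordance rows")
    best = min(rows, key=lambda r: (-round(abs(r.cdm_pct - r.original_pct), 9),
                                    r.phenotype))
    return round(abs(best.cdm_pct - best.original_pct), 9), best.phenotype


# ---------------------------------------------------------------------------
# coverage assembly from a bundle + ETL exclusion ledger
# ---------------------------------------------------------------------------

_NON_MAPPING_REASONS = {"missing-date", "rejected-patient", "zero-value-entity"}


def _excluded_lookup(exclusions: pd.DataFrame) -> dict[str, set[str]]:
    keep = exclusions[exclusions["reason"].isin(sorted(_NON_MAPPING_REASONS))]
    out: dict[str, set[str]] = {}
    for t, r in zip(keep["source_table"], keep["row_id"]):
        out.setdefault(t, set()).add(r)
    return out


def build_coverage(bundle: SourceBundle, cdm: CdmBundle, vocab: VocabularyStore
                   ) -> list[CoverageRow]:
    """One coverage row per source terminology, from events + the ETL ledger."""
    excluded = _excluded_lookup(cdm.exclusions)
    rows: list[CoverageRow] = []

    def events_frame(codes, flags):
        return pd.DataFrame({"code": pd.Series(codes, dtype="string"),
                             "excluded": pd.Series(flags, dtype=bool)})

    # primary-care diagnoses/observations (Read-like)
    ex = excluded.get("clinical", set())
    rows.append(vocab.coverage(events_frame(
        bundle.clinical["code"],
        [r in ex for r in bundle.clinical["row_id"]]), "read"))

    # hospital diagnoses + death causes (ICD-like)
    codes, flags = [], []
    ex_diag = excluded.get("hospital-diag", set())
    for r in bundle.hospital.itertuples(index=False):
        for i in range(1, N_DIAG_SLOTS + 1):
            code = getattr(r, f"diag_{i}")
            if pd.notna(code):
                codes.append(code)
                flags.append(f"{r.spell_id}:diag_{i}" in ex_diag)
    ex_death = excluded.get("death", set())
    cause_cols = [("underlying_cause", 0)] + \
        [(f"cause_{i}", i) for i in range(2, N_SECONDARY_CAUSES + 2)]
    for r in bundle.death.itertuples(index=False):
        for col, seq in cause_cols:
            code = getattr(r, col)
            if pd.notna(code):
                codes.append(code)
                flags.append(f"{r.patient_id}:c{seq}" in ex_death)
    rows.append(vocab.coverage(events_frame(codes, flags), "icd10"))

    # procedures (OPCS-like)
    codes, flags = [], []
    ex_proc = excluded.get("hospital-proc", set())
    for r in bundle.hospital.itertuples(index=False):
        for i in range(1, N_PROC_SLOTS + 1):
            code = getattr(r, f"proc_{i}")
            if pd.notna(code):
                codes.append(code)
                flags.append(f"{r.spell_id}:proc_{i}" in ex_proc)
    rows.append(vocab.coverage(events_frame(codes, flags), "opcs4"))

    # prescriptions (two-hop chain)
    ex = excluded.get("therapy", set())
    rows.append(vocab.coverage(events_frame(
        bundle.therapy["drug_code"],
        [r in ex for r in bundle.therapy["row_id"]]), "gemscript"))

    # units of measurement
    codes, flags = [], []
    for table in ("test", "additional"):
        frame = bundle.tables[table]
        ex = excluded.get(table, set())
        for r in frame.itertuples(index=False):
            if pd.notna(r.unit_code):
                codes.append(r.unit_code)
                flags.append(r.row_id in ex)
    rows.append(vocab.coverage(events_frame(codes, flags), "unit"))

    # wide-format entity fields, reported per source table
    for table in ("test", "additional"):
        frame = bundle.tables[table]
        ex = excluded.get(table, set())
        codes, flags = [], []
        for r in frame.itertuples(index=False):
            row_excluded = r.row_id in ex
            for i in range(1, 9):
                v = getattr(r, f"value_{i}")
                if pd.notna(v) and str(v) != "":
                    codes.append(f"{int(r.entity_type_id)}:{i}")
                    flags.append(row_excluded or f"{r.row_id}:f{i}" in ex)
        row = vocab.coverage(events_frame(codes, flags), "entity")
        row.vocabulary = f"entity-{table}"
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# full comparison report
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    labels: dict = field(default_factory=dict)
    demographics: list[dict] = field(default_factory=list)
    lifestyle: list[dict] = field(default_factory=list)
    biomarkers: list[dict] = field(default_factory=list)
    medications: list[dict] = field(default_factory=list)
    concordance: list[dict] = field(default_factory=list)
    coverage: list[dict] = field(default_factory=list)
    max_gap: dict = field(default_factory=dict)
    omissions: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls(**json.loads(text))

    @classmethod
    def read_json(cls, path: str | Path) -> "ComparisonReport":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))

    def to_markdown(self) -> str:
        out = ["# Source vs CDM comparison", ""]
        out.append("## Cohort")
        for k, v in sorted(self.labels.items()):
            out.append(f"- {k}: {v}")
        out += ["", "## Demographics and lifestyle",
                "| measure | source | CDM |", "|---|---|---|"]
        for row in self.demographics + self.lifestyle:
            out.append(f"| {row['measure']} | {row['source']} | {row['cdm']} |")
        out += ["", "## Clinical measures (n, median, IQR, mean, SD)",
                "| biomarker | source | CDM |", "|---|---|---|"]
        for row in self.biomarkers:
            out.append(f"| {row['name']} | {row['source']} | {row['cdm']} |")
        out += ["", "## Medication (%)", "| class | source | CDM |", "|---|---|---|"]
        for row in self.medications:
            out.append(f"| {row['name']} | {row['source']} | {row['cdm']} |")
        out += ["", "## Comorbidity concordance",
                "| phenotype | original % (n) | CDM % (n) | unmapped % (n) | "
                "incorrectly mapped % (n) |", "|---|---|---|---|---|"]
        for r in self.concordance:
            out.append(
                f"| {r['phenotype']} | {r['original_pct']} ({r['original_n']}) "
                f"| {r['cdm_pct']} ({r['cdm_n']}) | {r['unmapped_pct']} "
                f"({r['unmapped_n']}) | {r['incorrect_pct']} ({r['incorrect_n']}) |")
        if self.max_gap:
            out.append(f"\nLargest prevalence difference: {self.max_gap['value']}% "
                       f"({self.max_gap['phenotype']})")
        out += ["", "## Vocabulary mapping coverage",
                "| vocabulary | total terms | mapped terms % | used terms | "
                "used mapped % | events | excluded % | mapped events % |",
                "|---|---|---|---|---|---|---|---|"]
        for r in self.coverage:
            out.append(f"| {r['vocabulary']} | {r['total_terms']} "
                       f"| {r['total_mapped_terms_pct']} | {r['used_terms']} "
                       f"| {r['used_mapped_terms_pct']} | {r['total_events']} "
                       f"| {r['excluded_events_pct']} | {r['mapped_events_pct']} |")
        if self.omissions:
            out += ["", "## Omitted sections"] + [f"- {o}" for o in self.omissions]
        return "\n".join(out) + "\n"


def _fmt_summary(s: ph.BiomarkerSummary) -> str:
    if s.n == 0:
        return "n=0"
    return (f"n={s.n}, median={s.median:.2f}, IQR={s.iqr:.2f}, "
            f"mean={s.mean:.2f}, SD={s.sd:.2f}")


def assemble_reports(bundle: SourceBundle, cdm: CdmBundle, vocab: VocabularyStore,
                     definitions: dict[str, ph.PhenotypeDefinition],
                     cohort_phenotype: str = "hf",
                     rules: ph.CohortRules | None = None,
                     study_end=None) -> ComparisonReport:
    """Run every phenotype against both representations and compare.

    The comparison cohort is the full set of patients identified with the
    cohort phenotype (incident and prevalent); incident-cohort rules are
    applied on top for lifestyle, biomarker and medication summaries.
    """
    from .etl import EtlOptions
    study_end = study_end or EtlOptions().study_end
    report = ComparisonReport()
    defs = definitions

    for defn in defs.values():
        if defn.concept_set is None:
            ph.translate_codelist(defn, vocab)

    if cohort_phenotype not in defs:
        report.omissions.append(f"cohort phenotype {cohort_phenotype!r} undefined")
        return report

    results_src = {n: ph.find_patients_source(d, bundle) for n, d in defs.items()}
    results_cdm = {n: ph.find_patients_cdm(d, cdm) for n, d in defs.items()}

    hf_src = results_src[cohort_phenotype].patient_ids
    hf_cdm = results_cdm[cohort_phenotype].patient_ids
    report.labels["original_cohort_size"] = len(hf_src)
    report.labels["cdm_cohort_size"] = len(hf_cdm)
    report.labels["persons_rejected"] = int(
        (cdm.exclusions["source_table"] == "patient").sum())
    report.labels["visit_count"] = len(cdm.visit_occurrence)

    demo_src = ph.demographics_from_source(bundle, study_end)
    demo_cdm = ph.demographics_from_cdm(cdm)
    cohort_src = ph.build_hf_cohort(results_src[cohort_phenotype], demo_src, rules)
    cohort_cdm = ph.build_hf_cohort(results_cdm[cohort_phenotype], demo_cdm, rules)
    report.labels["incident_cohort_source"] = int(cohort_src["included"].sum())
    report.labels["incident_cohort_cdm"] = int(cohort_cdm["included"].sum())

    # demographics ----------------------------------------------------------
    pat = bundle.patient.set_index("patient_id")
    person = cdm.person.set_index("patient_source_id")

    def female_pct(ids, table, col):
        ids = [i for i in ids if i in table.index]
        if not ids:
            return 0.0
        n_f = int((table.loc[ids, col] == "F").sum())
        return pct(n_f, len(ids))

    report.demographics.append({
        "measure": "female_pct",
        "source": female_pct(hf_src, pat, "sex"),
        "cdm": female_pct(hf_cdm, person, "sex")})

    hosp_eth: dict[str, str] = {}
    if len(bundle.hospital):
        for r in bundle.hospital.sort_values("spell_id").itertuples(index=False):
            if pd.notna(r.ethnicity_code) and r.patient_id not in hosp_eth:
                hosp_eth[r.patient_id] = r.ethnicity_code

    def caucasian_pct_source(ids):
        known = []
        for pid in ids:
            v = pat.loc[pid, "ethnicity_code"] if pid in pat.index else None
            if v is None or pd.isna(v):
                v = hosp_eth.get(pid)
            if v is not None and pd.notna(v):
                known.append(v)
        return pct(sum(1 for v in known if v == "ETH1"), len(known)) if known else 0.0

    def caucasian_pct_cdm(ids):
        known = [person.loc[pid, "ethnicity_source_code"] for pid in ids
                 if pid in person.index
                 and pd.notna(person.loc[pid, "ethnicity_source_code"])]
        return pct(sum(1 for v in known if v == "ETH1"), len(known)) if known else 0.0

    report.demographics.append({
        "measure": "caucasian_pct",
        "source": caucasian_pct_source(hf_src),
        "cdm": caucasian_pct_cdm(hf_cdm)})

    death_q = {}
    if len(bundle.death):
        for r in bundle.death.itertuples(index=False):
            if pd.notna(r.deprivation_quintile):
                death_q[r.patient_id] = int(r.deprivation_quintile)

    def deprived_pct(ids, lookup):
        known = [lookup[pid] for pid in ids if pid in lookup]
        return pct(sum(1 for q in known if q == 5), len(known)) if known else 0.0

    cdm_q = {pid: int(q) for pid, q in
             zip(cdm.person["patient_source_id"], cdm.person["deprivation_quintile"])
             if pd.notna(q)}
    report.demographics.append({
        "measure": "most_deprived_fifth_pct",
        "source": deprived_pct(hf_src, death_q),
        "cdm": deprived_pct(hf_cdm, cdm_q)})

    # lifestyle ---------------------------------------------------------------
    if "smoking" in defs:
        smoke_src = ph.smoking_summary(results_src["smoking"], cohort_src)
        smoke_cdm = ph.smoking_summary(results_cdm["smoking"], cohort_cdm)
        for status in sorted(set(smoke_src) | set(smoke_cdm)):
            report.lifestyle.append({
                "measure": f"smoking_{status}_pct",
                "source": smoke_src.get(status, (0, 0.0))[1],
                "cdm": smoke_cdm.get(status, (0, 0.0))[1]})
    else:
        report.omissions.append("smoking definition missing")

    # biomarkers and medications ---------------------------------------------
    for name, defn in sorted(defs.items()):
        if defn.kind == "biomarker":
            s = ph.summarize_biomarker(results_src[name], cohort_src)
            c = ph.summarize_biomarker(results_cdm[name], cohort_cdm)
            report.biomarkers.append({"name": name, "source": _fmt_summary(s),
                                      "cdm": _fmt_summary(c),
                                      "source_stats": s.as_tuple(),
                                      "cdm_stats": c.as_tuple()})
        elif defn.kind == "medication-class":
            report.medications.append({
                "name": name,
                "source": ph.medication_flag(results_src[name], cohort_src),
                "cdm": ph.medication_flag(results_cdm[name], cohort_cdm)})

    # comorbidity concordance -------------------------------------------------
    rows = []
    for name, defn in sorted(defs.items()):
        if defn.kind != "condition" or name == cohort_phenotype:
            continue
        row = concordance(name,
                          results_src[name].patient_ids & hf_src,
                          results_cdm[name].patient_ids & hf_cdm,
                          len(hf_src), len(hf_cdm))
        rows.append(row)
    report.concordance = [r.as_dict() for r in rows]
    if rows:
        value, name = max_prevalence_gap(rows)
        report.max_gap = {"value": value, "phenotype": name}

    report.coverage = [r.as_dict() for r in build_coverage(bundle, cdm, vocab)]
    return report
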