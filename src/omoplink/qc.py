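"""Data-quality profiling of a CDM bundle.

Four check families, mirroring the defect classes that matter for
longitudinal EHR conversions:

1. records dated outside the person's observation period, per domain
   (boundary days count as inside; a person without any observation period
   counts all their events as outside);
2. event rows referencing a person absent from the person table;
3. event rows whose visit reference resolves to no visit (dangling
   encounter references, e.g. prescriptions pointing at consultations that
   were never recorded);
4. visits whose end date precedes their start date.

The checks are read-only: the bundle is never modified.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import CDM_EVENT_TABLES, CdmBundle
from .rounding import pct

_DATE_COL = {
    "condition_occurrence": "condition_start_date",
    "procedure_occurrence": "procedure_date",
    "drug_exposure": "drug_exposure_start_date",
    "measurement": "measurement_date",
    "observation": "observation_date",
    "death": "death_date",
}
_VISIT_TABLES = ("condition_occurrence", "procedure_occurrence", "drug_exposure")


@dataclass
class QualityReport:
    outside_period_pct: dict[str, float] = field(default_factory=dict)
    outside_period_n: dict[str, int] = field(default_factory=dict)
    dangling_person: dict[str, int] = field(default_factory=dict)
    dangling_visit: dict[str, int] = field(default_factory=dict)
    visit_end_before_start: int = 0
    totals: dict[str, int] = field(default_factory=dict)

    def total_outside(self) -> int:
        return sum(self.outside_period_n.values())

    def total_dangling_person(self) -> int:
        return sum(self.dangling_person.values())

    def total_dangling_visit(self) -> int:
        return sum(self.dangling_visit.values())

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def run_checks(cdm: CdmBundle) -> QualityReport:
    report = QualityReport()
    periods = {}
    for r in cdm.observation_period.itertuples(index=False):
        periods[int(r.person_id)] = (r.observation_period_start_date,
                                     r.observation_period_end_date)
    persons = set(cdm.person["person_id"].astype(str).map(int))
    visit_ids = set(pd.to_numeric(cdm.visit_occurrence["visit_occurrence_id"]).tolist())

    tables = CDM_EVENT_TABLES + ("visit_occurrence",)
    for name in tables:
        frame = cdm.tables[name]
        date_col = _DATE_COL.get(name, "visit_start_date")
        total = len(frame)
        report.totals[name] = total
        outside = dangling_p = 0
        for r in frame.itertuples(index=False):
            person_id = int(r.person_id)
            if person_id not in persons:
                dangling_p += 1
            when = getattr(r, date_col)
            period = periods.get(person_id)
            if period is None:
                outside += 1  # no observation period at all
            elif pd.notna(when) and not (period[0] <= when <= period[1]):
                outside += 1
        report.outside_period_n[name] = outside
        report.outside_period_pct[name] = pct(outside, total, places=1) if total else 0.0
        report.dangling_person[name] = dangling_p

    for name in _VISIT_TABLES:
        frame = cdm.tables[name]
        dangling = 0
        for r in frame.itertuples(index=False):
            if int(r.invalid_visit_flag) == 1:
                dangling += 1
            elif pd.notna(r.visit_occurrence_id) \
                    and int(r.visit_occurrence_id) not in visit_ids:
                dangling += 1
        report.dangling_visit[name] = dangling

    if len(cdm.visit_occurrence):
        bad = (cdm.visit_occurrence["visit_end_date"]
               < cdm.visit_occurrence["visit_start_date"])
        report.visit_end_before_start = int(bad.sum())
    return report


def render_dashboard(report: QualityReport, directory: str | Path) -> tuple[Path, Path]:
    """Deterministic qc.json + qc.md tabular summaries."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    json_path = directory / "qc.json"
    json_path.write_text(report.to_json(), encoding="utf-8")

    lines = ["# Data quality summary", "",
             "| table | rows | outside period n (%) | dangling person | "
             "dangling visit |", "|---|---|---|---|---|"]
    for name in sorted(report.totals):
        lines.append(
            f"| {name} | {report.totals[name]} "
            f"| {report.outside_period_n.get(name, 0)} "
            f"({report.outside_period_pct.get(name, 0.0)}%) "
            f"| {report.dangling_person.get(name, 0)} "
            f"| {report.dangling_visit.get(name, '-')} |")
    lines += ["", f"Visits with end date before start date: "
                  f"{report.visit_end_before_start}",
              f"Total records outside observation periods: {report.total_outside()}",
              f"Total dangling person references: {report.total_dangling_person()}",
              f"Total dangling visit references: {report.total_dangling_visit()}", ""]
    md_path = directory / "qc.md"
    md_path.write_text("\n".join(lines), encoding="utf-8")
    return json_path, md_path
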