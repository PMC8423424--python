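"""Reading, writing and validating the delimited tables.

One CSV dialect everywhere: comma separated, double-quote escaping, UTF-8,
LF line endings, header row, ISO-8601 dates, empty string for null.
Unparseable cells never abort a read — they become null and are logged as
:class:`CellIssue` records so that validation is total.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError
from .schemas import CDM_SCHEMAS, SOURCE_SCHEMAS, TableSchema

_DATE_FMT = "%Y-%m-%d"


@dataclass(frozen=True)
class CellIssue:
    """One non-conforming cell: where it was and why it was nulled."""

    table: str
    row: int
    column: str
    reason: str


@dataclass
class ReadResult:
    frame: pd.DataFrame
    issues: list[CellIssue] = field(default_factory=list)


def _string_series(s: pd.Series) -> pd.Series:
    s = s.astype("string")
    return s.mask(s == "", pd.NA)


def coerce_frame(df: pd.DataFrame, schema: TableSchema,
                 issues: list[CellIssue] | None = None) -> pd.DataFrame:
    """Normalize a raw (string-ish) frame to the schema's canonical dtypes.

    Both ``read_table`` and the synthetic generator funnel through this, so
    a written-then-read table compares equal to the in-memory original.
    """
    out = pd.DataFrame(index=df.index)
    for col in schema.columns:
        if col.name not in df.columns:
            raise SchemaError(f"table {schema.name!r}: missing column {col.name!r}")
        s = df[col.name]
        if col.kind == "date":
            raw = _string_series(s) if s.dtype != "datetime64[ns]" else None
            if raw is not None:
                parsed = pd.to_datetime(raw, format=_DATE_FMT, errors="coerce")
                if issues is not None:
                    bad = raw.notna() & parsed.isna()
                    for i in np.flatnonzero(bad.to_numpy()):
                        issues.append(CellIssue(schema.name, int(i), col.name,
                                                f"unparseable date {raw.iloc[i]!r}"))
                s = parsed
        elif col.kind in ("integer", "quintile"):
            if s.dtype != "Int64":
                raw = _string_series(s.astype("string"))
                parsed = pd.to_numeric(raw, errors="coerce").astype("Int64")
                if issues is not None:
                    bad = raw.notna() & parsed.isna()
                    for i in np.flatnonzero(bad.to_numpy()):
                        issues.append(CellIssue(schema.name, int(i), col.name,
                                                f"not an integer: {raw.iloc[i]!r}"))
                s = parsed
            else:
                s = s.copy()
            if col.kind == "quintile":
                bad = s.notna() & ~s.isin([1, 2, 3, 4, 5])
                if issues is not None:
                    for i in np.flatnonzero(bad.to_numpy()):
                        issues.append(CellIssue(schema.name, int(i), col.name,
                                                f"quintile out of range: {s.iloc[i]}"))
                s = s.mask(bad)
        elif col.kind == "real":
            if s.dtype != float:
                raw = _string_series(s.astype("string"))
                parsed = pd.to_numeric(raw, errors="coerce").astype(float)
                if issues is not None:
                    bad = raw.notna() & parsed.isna()
                    for i in np.flatnonzero(bad.to_numpy()):
                        issues.append(CellIssue(schema.name, int(i), col.name,
                                                f"not a number: {raw.iloc[i]!r}"))
                s = parsed
        else:  # id / code / text
            s = _string_series(s.astype("string"))
        if not col.nullable and issues is not None:
            for i in np.flatnonzero(s.isna().to_numpy()):
                issues.append(CellIssue(schema.name, int(i), col.name, "null in non-nullable column"))
        out[col.name] = s

    pk = out[schema.primary_key]
    if pk.isna().any():
        raise IntegrityError(f"table {schema.name!r}: null primary key {schema.primary_key!r}")
    if pk.duplicated().any():
        dups = sorted(pk[pk.duplicated()].unique().tolist())[:5]
        raise IntegrityError(
            f"table {schema.name!r}: duplicate {schema.primary_key!r} values {dups}")
    return out


def empty_frame(schema: TableSchema) -> pd.DataFrame:
    data = {}
    for col in schema.columns:
        dtype = {"date": "datetime64[ns]", "integer": "Int64", "quintile": "Int64",
                 "real": float}.get(col.kind, "string")
        data[col.name] = pd.Series([], dtype=dtype)
    return pd.DataFrame(data)


def read_table(path: str | Path, schema: TableSchema) -> ReadResult:
    """Read one delimited table, typing and validating against *schema*.

    Row order is preserved; unparseable dates/numbers become null and are
    reported in ``issues``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype="string", keep_default_na=False,
                      na_values=[], encoding="utf-8")
    issues: list[CellIssue] = []
    if len(raw) == 0 and raw.columns.size and set(schema.column_names) <= set(raw.columns):
        return ReadResult(empty_frame(schema), issues)
    frame = coerce_frame(raw, schema, issues)
    return ReadResult(frame, issues)


def write_table(frame: pd.DataFrame, path: str | Path, schema: TableSchema) -> None:
    """Write a table in the canonical dialect with deterministic column order."""
    out = pd.DataFrame(index=frame.index)
    for col in schema.columns:
        if col.name not in frame.columns:
            raise SchemaError(f"table {schema.name!r}: missing column {col.name!r}")
        s = frame[col.name]
        if col.kind == "date":
            s = pd.to_datetime(s).dt.strftime(_DATE_FMT)
        out[col.name] = s
    out.to_csv(path, index=False, na_rep="", encoding="utf-8",
               lineterminator="\n", quoting=csv.QUOTE_MINIMAL)


def _frames_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    try:
        pd.testing.assert_frame_equal(a, b, check_dtype=False)
        return True
    except AssertionError:
        return False


@dataclass
class SourceBundle:
    """The raw three-source EHR extract: one frame per delimited table."""

    patient: pd.DataFrame
    practice: pd.DataFrame
    consultation: pd.DataFrame
    clinical: pd.DataFrame
    therapy: pd.DataFrame
    test: pd.DataFrame
    additional: pd.DataFrame
    hospital: pd.DataFrame
    death: pd.DataFrame

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def validate(self) -> None:
        for name, frame in self.tables.items():
            coerce_frame(frame, SOURCE_SCHEMAS[name])  # dtype + key checks
        patients = set(self.patient["patient_id"])
        for name in ("consultation", "clinical", "therapy", "test",
                     "additional", "hospital", "death"):
            refs = set(self.tables[name]["patient_id"].dropna())
            orphans = refs - patients
            if orphans:
                raise IntegrityError(
                    f"table {name!r}: patient references not in patient table: "
                    f"{sorted(orphans)[:5]}")
        diag_cols = [c for c in self.hospital.columns if c.startswith("diag_")]
        if len(self.hospital):
            any_diag = self.hospital[diag_cols].notna().any(axis=1)
            bad = any_diag & self.hospital["diag_1"].isna()
            if bad.any():
                raise IntegrityError("hospital: diagnosis slot 1 empty while later slots used")

    def write(self, directory: str | Path) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self.tables.items():
            p = directory / f"{name}.csv"
            write_table(frame, p, SOURCE_SCHEMAS[name])
            written.append(p)
        return written

    @classmethod
    def read(cls, directory: str | Path) -> "SourceBundle":
        directory = Path(directory)
        frames = {}
        for name in SOURCE_SCHEMAS:
            frames[name] = read_table(directory / f"{name}.csv", SOURCE_SCHEMAS[name]).frame
        return cls(**frames)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SourceBundle):
            return NotImplemented
        return all(_frames_equal(self.tables[n], other.tables[n]) for n in self.tables)


CDM_EVENT_TABLES = ("condition_occurrence", "procedure_occurrence", "drug_exposure",
                    "measurement", "observation", "death")


@dataclass
class CdmBundle:
    """Populated CDM-subset tables plus the exclusion and mapping ledgers."""

    person: pd.DataFrame
    observation_period: pd.DataFrame
    visit_occurrence: pd.DataFrame
    condition_occurrence: pd.DataFrame
    procedure_occurrence: pd.DataFrame
    drug_exposure: pd.DataFrame
    drug_era: pd.DataFrame
    measurement: pd.DataFrame
    observation: pd.DataFrame
    death: pd.DataFrame
    exclusions: pd.DataFrame
    code_mappings: pd.DataFrame

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    @classmethod
    def empty(cls) -> "CdmBundle":
        return cls(**{name: empty_frame(schema) for name, schema in CDM_SCHEMAS.items()})

    def validate(self) -> None:
        persons = set(pd.to_numeric(self.person["person_id"]).tolist())
        for name in CDM_EVENT_TABLES + ("visit_occurrence",):
            frame = self.tables[name]
            if not len(frame):
                continue
            refs = set(pd.to_numeric(frame["person_id"]).dropna().tolist())
            dangling = refs - persons
            if dangling:
                raise IntegrityError(
                    f"table {name!r}: person references not in person: "
                    f"{sorted(dangling)[:5]}")
        if self.observation_period["person_id"].duplicated().any():
            raise IntegrityError("observation_period: more than one row for a person")
        if self.visit_occurrence["visit_occurrence_id"].duplicated().any():
            raise IntegrityError("visit_occurrence: duplicate visit ids")

    def write(self, directory: str | Path, overwrite: bool = False) -> list[Path]:
        """Write one CSV per table; refuses a directory already holding a CDM.

        The single-shot contract: the ETL is never re-run onto its own output.
        """
        self.validate()
        directory = Path(directory)
        marker = directory / "person.csv"
        if marker.exists() and not overwrite:
            raise IntegrityError(
                f"{directory} already contains a CDM bundle; refusing to overwrite")
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self.tables.items():
            p = directory / f"{name}.csv"
            write_table(frame, p, CDM_SCHEMAS[name])
            written.append(p)
        return written

    @classmethod
    def read(cls, directory: str | Path) -> "CdmBundle":
        directory = Path(directory)
        frames = {}
        for name in CDM_SCHEMAS:
            frames[name] = read_table(directory / f"{name}.csv", CDM_SCHEMAS[name]).frame
        return cls(**frames)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CdmBundle):
            return NotImplemented
        return all(_frames_equal(self.tables[n], other.tables[n]) for n in self.tables)
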