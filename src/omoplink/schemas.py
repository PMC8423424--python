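"""Declarative table schemas for the source bundle, vocabulary bundle and CDM subset.

Every delimited file the pipeline reads or writes is described here once:
column order, semantic type and nullability. ``io.read_table`` /
``io.write_table`` enforce these declarations so that parsing and
validation live in a single place.

Semantic column kinds:

- ``id``        opaque identifier, stored as string; the *first* id column of a
                schema is its primary key (unique, never null)
- ``date``      ISO-8601 calendar date
- ``code``      clinical terminology code, stored as string
- ``integer``   whole number (nullable integers use pandas ``Int64``)
- ``real``      floating point
- ``text``      free string
- ``quintile``  integer restricted to 1..5 (deprivation fifths)
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import SchemaError

KINDS = {"id", "date", "code", "integer", "real", "text", "quintile"}


@dataclass(frozen=True)
class Column:
    name: str
    kind: str
    nullable: bool = True

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")


@dataclass(frozen=True)
class TableSchema:
    """Ordered column declaration for one delimited table."""

    name: str
    columns: tuple[Column, ...] = field(default_factory=tuple)

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in schema {self.name!r}")
        if not any(c.kind == "id" for c in self.columns):
            raise SchemaError(f"schema {self.name!r} has no id column")

    @property
    def column_names(self) -> list[str]:
        return [c.name for c in self.columns]

    @property
    def primary_key(self) -> str:
        return next(c.name for c in self.columns if c.kind == "id")

    def column(self, name: str) -> Column:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"no column {name!r} in schema {self.name!r}")


def _cols(*specs) -> tuple[Column, ...]:
    return tuple(Column(*s) for s in specs)


# --------------------------------------------------------------------------
# Source bundle: primary care (patient/practice/consultation/clinical/therapy/
# test/additional), hospitalization (hospital) and mortality (death).
# --------------------------------------------------------------------------

N_DIAG_SLOTS = 20       # hospital discharge diagnoses per spell
N_PROC_SLOTS = 8        # hospital procedures per spell
N_SECONDARY_CAUSES = 14  # secondary causes of death
N_ENTITY_FIELDS = 8     # wide value slots per test/additional row

_entity_cols = _cols(
    ("row_id", "id", False),
    ("patient_id", "id", False),
    ("event_date", "date", True),
    ("entity_type_id", "integer", False),
    *((f"value_{i}", "text", True) for i in range(1, N_ENTITY_FIELDS + 1)),
    ("unit_code", "code", True),
)

SOURCE_SCHEMAS: dict[str, TableSchema] = {
    "patient": TableSchema("patient", _cols(
        ("patient_id", "id", False),
        ("sex", "text", False),
        ("year_of_birth", "integer", False),
        ("ethnicity_code", "code", True),
        ("registration_date", "date", True),
        ("transfer_out_date", "date", True),
        ("practice_id", "id", False),
        ("death_date", "date", True),
    )),
    "practice": TableSchema("practice", _cols(
        ("practice_id", "id", False),
        ("up_to_standard_date", "date", False),
        ("last_collection_date", "date", False),
    )),
    "consultation": TableSchema("consultation", _cols(
        ("consultation_id", "id", False),
        ("patient_id", "id", False),
        ("event_date", "date", True),
    )),
    "clinical": TableSchema("clinical", _cols(
        ("row_id", "id", False),
        ("patient_id", "id", False),
        ("consultation_id", "id", True),
        ("event_date", "date", True),
        ("code", "code", False),
    )),
    "therapy": TableSchema("therapy", _cols(
        ("row_id", "id", False),
        ("patient_id", "id", False),
        ("consultation_id", "id", True),
        ("event_date", "date", True),
        ("drug_code", "code", False),
    )),
    "test": TableSchema("test", _entity_cols),
    "additional": TableSchema("additional", _entity_cols),
    "hospital": TableSchema("hospital", _cols(
        ("spell_id", "id", False),
        ("patient_id", "id", False),
        ("admission_date", "date", True),
        *((f"diag_{i}", "code", True) for i in range(1, N_DIAG_SLOTS + 1)),
        *((f"proc_{i}", "code", True) for i in range(1, N_PROC_SLOTS + 1)),
        ("ethnicity_code", "code", True),
    )),
    "death": TableSchema("death", _cols(
        ("patient_id", "id", False),
        ("death_date", "date", False),
        ("underlying_cause", "code", False),
        *((f"cause_{i}", "code", True) for i in range(2, N_SECONDARY_CAUSES + 2)),
        ("deprivation_quintile", "quintile", True),
    )),
}


# --------------------------------------------------------------------------
# Vocabulary bundle.
# --------------------------------------------------------------------------

VOCAB_SCHEMAS: dict[str, TableSchema] = {
    "concept": TableSchema("concept", _cols(
        ("concept_id", "id", False),
        ("code", "code", False),
        ("vocabulary", "text", False),
        ("domain", "text", True),
        ("standard", "integer", False),
    )),
    "mapping_edge": TableSchema("mapping_edge", _cols(
        ("edge_id", "id", False),
        ("source_code", "code", False),
        ("source_vocabulary", "text", False),
        ("target_concept_id", "integer", False),
        ("relationship", "text", False),
    )),
    "entity_field_map": TableSchema("entity_field_map", _cols(
        ("map_id", "id", False),
        ("entity_type_id", "integer", False),
        ("field_index", "integer", False),
        ("target_concept_id", "integer", True),
        ("semantics", "text", False),
    )),
    "unit_map": TableSchema("unit_map", _cols(
        ("unit_code", "id", False),
        ("target_concept_id", "integer", True),
    )),
    "source_term": TableSchema("source_term", _cols(
        ("term_id", "id", False),
        ("vocabulary", "text", False),
        ("code", "code", False),
    )),
}


# --------------------------------------------------------------------------
# CDM subset (CDM 5.2 clinical + derived tables actually populated) plus the
# two provenance ledgers.
# --------------------------------------------------------------------------

def _event_cols(concept_col: str, date_col: str, extra=()) -> tuple[Column, ...]:
    return _cols(
        ("row_id", "id", False),
        ("person_id", "integer", False),
        (concept_col, "integer", False),
        (date_col, "date", True),
        ("visit_occurrence_id", "integer", True),
        ("visit_source_value", "text", True),
        ("invalid_visit_flag", "integer", False),
        ("source_code", "code", True),
        ("source_vocabulary", "text", True),
        ("source_table", "text", False),
        ("source_row_id", "text", False),
        *extra,
    )


CDM_SCHEMAS: dict[str, TableSchema] = {
    "person": TableSchema("person", _cols(
        ("person_id", "id", False),
        ("patient_source_id", "id", False),
        ("sex", "text", False),
        ("year_of_birth", "integer", False),
        ("ethnicity_concept_id", "integer", True),
        ("ethnicity_source_code", "code", True),
        ("deprivation_quintile", "quintile", True),
    )),
    "observation_period": TableSchema("observation_period", _cols(
        ("person_id", "id", False),
        ("observation_period_start_date", "date", False),
        ("observation_period_end_date", "date", False),
    )),
    "visit_occurrence": TableSchema("visit_occurrence", _cols(
        ("visit_occurrence_id", "id", False),
        ("person_id", "integer", False),
        ("visit_start_date", "date", False),
        ("visit_end_date", "date", False),
        ("visit_source", "text", False),
        ("visit_source_value", "text", False),
    )),
    "condition_occurrence": TableSchema(
        "condition_occurrence", _event_cols("condition_concept_id", "condition_start_date")),
    "procedure_occurrence": TableSchema(
        "procedure_occurrence", _event_cols("procedure_concept_id", "procedure_date")),
    "drug_exposure": TableSchema(
        "drug_exposure", _event_cols("drug_concept_id", "drug_exposure_start_date")),
    "drug_era": TableSchema("drug_era", _cols(
        ("era_id", "id", False),
        ("person_id", "integer", False),
        ("drug_concept_id", "integer", False),
        ("drug_era_start_date", "date", False),
        ("drug_era_end_date", "date", False),
        ("drug_exposure_count", "integer", False),
    )),
    "measurement": TableSchema(
        "measurement",
        _event_cols("measurement_concept_id", "measurement_date", extra=(
            ("value_as_number", "real", True),
            ("unit_concept_id", "integer", True),
            ("unit_source_code", "code", True),
        ))),
    "observation": TableSchema(
        "observation",
        _event_cols("observation_concept_id", "observation_date", extra=(
            ("value_as_string", "text", True),
        ))),
    "death": TableSchema("death", _cols(
        ("row_id", "id", False),
        ("person_id", "integer", False),
        ("death_date", "date", False),
        ("cause_concept_id", "integer", True),
        ("cause_seq", "integer", False),
        ("source_code", "code", True),
        ("source_table", "text", False),
        ("source_row_id", "text", False),
    )),
    "exclusions": TableSchema("exclusions", _cols(
        ("ledger_id", "id", False),
        ("source_table", "text", False),
        ("row_id", "text", False),
        ("reason", "text", False),
    )),
    "code_mappings": TableSchema("code_mappings", _cols(
        ("ledger_id", "id", False),
        ("source_code", "code", False),
        ("vocabulary", "text", False),
        ("target_concept_id", "integer", True),
    )),
}

#: exclusion ledger reason codes
EXCLUSION_REASONS = (
    "missing-date",
    "rejected-patient",
    "inconsistent-observation-period",
    "unmapped-code",
    "zero-value-entity",
)
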