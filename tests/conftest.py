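"""Shared fixtures: generated worlds at two defect settings plus a hand-built
micro bundle whose every row exercises one transformation rule."""

from datetime import date

import pandas as pd
import pytest

from omoplink.etl import run_etl
from omoplink.io import SourceBundle, coerce_frame, empty_frame
from omoplink.schemas import SOURCE_SCHEMAS
from omoplink.synth import DEFECT_NAMES, GeneratorConfig, generate_world
from omoplink.vocab import Concept, EntityField, VocabularyStore

ZERO_DEFECTS = {name: 0.0 for name in DEFECT_NAMES}


def clean_config(**overrides) -> GeneratorConfig:
    """Defect-free study with a fully mapped vocabulary."""
    kwargs = dict(n_patients=300, seed=11, defect_rates=dict(ZERO_DEFECTS),
                  drug_chain_break_fraction=0.0, entity_unmapped_field_rate=0.0,
                  ethnicity_disagreement_rate=0.0)
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


@pytest.fixture(scope="session")
def clean_world():
    return generate_world(clean_config())


@pytest.fixture(scope="session")
def clean_cdm(clean_world):
    return run_etl(clean_world.bundle, clean_world.vocab).cdm


@pytest.fixture(scope="session")
def defect_world():
    """Elevated defect rates so every defect family is well represented."""
    return generate_world(GeneratorConfig(
        n_patients=300, seed=17,
        defect_rates={"missing_event_date": 0.05,
                      "inverted_observation_period": 0.02,
                      "orphan_therapy_row": 0.10,
                      "unmappable_code": 0.05,
                      "zero_value_entity_row": 0.20}))


@pytest.fixture(scope="session")
def defect_cdm(defect_world):
    return run_etl(defect_world.bundle, defect_world.vocab).cdm


def make_frame(table: str, rows: list[dict]) -> pd.DataFrame:
    schema = SOURCE_SCHEMAS[table]
    if not rows:
        return empty_frame(schema)
    frame = pd.DataFrame(rows)
    for col in schema.column_names:
        if col not in frame.columns:
            frame[col] = None
    return coerce_frame(frame[schema.column_names], schema)


def micro_vocab() -> VocabularyStore:
    v = VocabularyStore()
    for cid, code, voc, domain, std in [
            (1, "SCT-A", "snomed", "condition", True),
            (2, "SCT-B", "snomed", "observation", True),
            (3, "SCT-I", "snomed", "condition", True),
            (4, "SCT-P", "snomed", "procedure", True),
            (5, "RX-A", "rxnorm", "drug", True),
            (6, "LOINC-X", "loinc", "measurement", True),
            (8, "UCUM-1", "ucum", "unit", True),
            (9, "ETHN-1", "ethnicity-std", "observation", True),
            (10, "ETHN-2", "ethnicity-std", "observation", True),
            (11, "DA", "dmd", "drug", False),
            (12, "DB", "dmd", "drug", False)]:
        v.add_concept(Concept(cid, code, voc, domain, std))
    v.add_edge("RA", "read", 1)
    v.add_edge("RB", "read", 2)
    v.add_edge("IA", "icd10", 3)
    v.add_edge("PA", "opcs4", 4)
    v.add_edge("GA", "gemscript", 11, relationship="translates-to")
    v.add_edge("DA", "dmd", 5)
    v.add_edge("GBRK", "gemscript", 12, relationship="translates-to")  # hop 2 missing
    v.add_edge("ETH1", "ethnicity", 9)
    v.add_edge("ETH2", "ethnicity", 10)
    v.add_edge("U1", "unit", 8)
    v.unit_map["U1"] = 8
    v.register_term("read", "RUNMAPPED")
    v.entity_map[(9, 1)] = EntityField(6, "numeric")
    v.entity_map[(9, 2)] = EntityField(6, "ignore-zero")
    v.add_edge("9:1", "entity", 6)
    v.add_edge("9:2", "entity", 6)
    return v


@pytest.fixture()
def micro():
    """Three patients covering period rules, rejection, ethnicity, orphans,
    chain breaks, many-to-one-free routing and zero-valued entity fields."""
    bundle = SourceBundle(
        patient=make_frame("patient", [
            dict(patient_id="P1", sex="F", year_of_birth=1950,
                 ethnicity_code="ETH1", registration_date="2000-01-01",
                 practice_id="PR1"),
            dict(patient_id="P2", sex="M", year_of_birth=1960,
                 registration_date="2000-01-01", practice_id="PR2"),
            dict(patient_id="P3", sex="M", year_of_birth=1940,
                 ethnicity_code="ETH1", registration_date="2000-02-02",
                 practice_id="PR1", death_date="2006-06-06"),
        ]),
        practice=make_frame("practice", [
            dict(practice_id="PR1", up_to_standard_date="1999-06-01",
                 last_collection_date="2010-01-01"),
            # up-to-standard after last collection: inverted period
            dict(practice_id="PR2", up_to_standard_date="2017-01-01",
                 last_collection_date="2010-01-01"),
        ]),
        consultation=make_frame("consultation", [
            dict(consultation_id="C1", patient_id="P1", event_date="2001-05-05"),
            dict(consultation_id="C2", patient_id="P1"),  # undated
            dict(consultation_id="C3", patient_id="P3", event_date="2005-01-01"),
            dict(consultation_id="C4", patient_id="P2", event_date="2005-01-01"),
        ]),
        clinical=make_frame("clinical", [
            dict(row_id="L1", patient_id="P1", consultation_id="C1",
                 event_date="2001-05-05", code="RA"),
            dict(row_id="L2", patient_id="P1", consultation_id="C1",
                 event_date="2001-05-05", code="RB"),
            dict(row_id="L3", patient_id="P2", consultation_id="C4",
                 event_date="2005-01-01", code="RA"),       # rejected patient
            dict(row_id="L4", patient_id="P3", consultation_id="C3",
                 event_date="2005-01-01", code="RUNMAPPED"),
        ]),
        therapy=make_frame("therapy", [
            dict(row_id="T1", patient_id="P1", consultation_id="CORPHAN",
                 event_date="2002-02-02", drug_code="GA"),  # dangling encounter
            dict(row_id="T2", patient_id="P1", consultation_id="C1",
                 event_date="2001-05-05", drug_code="GBRK"),  # broken chain
        ]),
        test=make_frame("test", [
            dict(row_id="E1", patient_id="P1", event_date="2003-03-03",
                 entity_type_id=9, value_1="7.5", value_2="0", unit_code="U1"),
        ]),
        additional=make_frame("additional", []),
        hospital=make_frame("hospital", [
            dict(spell_id="H1", patient_id="P3", admission_date="2005-03-03",
                 diag_1="IA", proc_1="PA", ethnicity_code="ETH2"),
        ]),
        death=make_frame("death", [
            dict(patient_id="P3", death_date="2006-06-06",
                 underlying_cause="IA", deprivation_quintile=5),
        ]),
    )
    return bundle, micro_vocab()


STUDY_END = date(2016, 3, 8)
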