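"""ETL rules: periods, person assembly, visits, routing, eras, conservation."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from omoplink.etl import (EtlOptions, build_observation_periods, build_person,
                          derive_drug_eras, run_etl)
from omoplink.io import coerce_frame, empty_frame
from omoplink.schemas import CDM_SCHEMAS

from .conftest import STUDY_END


@pytest.fixture()
def micro_cdm(micro):
    bundle, vocab = micro
    return run_etl(bundle, vocab, EtlOptions(study_end=STUDY_END)).cdm


class TestObservationPeriod:
    def test_max_min_rule(self, micro):
        bundle, _ = micro
        periods, _ = build_observation_periods(bundle, STUDY_END)
        p1 = periods.set_index("patient_id").loc["P1"]
        assert p1["period_start"] == pd.Timestamp("2000-01-01")
        assert p1["period_end"] == pd.Timestamp("2010-01-01")

    def test_death_bounds_period_end(self, micro):
        bundle, _ = micro
        periods, _ = build_observation_periods(bundle, STUDY_END)
        p3 = periods.set_index("patient_id").loc["P3"]
        assert p3["period_end"] == pd.Timestamp("2006-06-06")

    def test_inverted_period_is_rejected(self, micro):
        bundle, _ = micro
        periods, rejections = build_observation_periods(bundle, STUDY_END)
        assert "P2" not in set(periods["patient_id"])
        assert rejections.set_index("patient_id").loc["P2", "reason"] \
            == "inconsistent-observation-period"

    def test_rejected_patient_contributes_zero_cdm_rows(self, micro_cdm):
        rejected_person_ids = set()
        for r in micro_cdm.person.itertuples(index=False):
            rejected_person_ids.add(r.patient_source_id)
        assert "P2" not in rejected_person_ids
        for name in ("condition_occurrence", "drug_exposure", "visit_occurrence",
                     "measurement", "observation", "death"):
            frame = micro_cdm.tables[name]
            if "source_row_id" in frame.columns:
                assert "L3" not in set(frame["source_row_id"])
        excl = micro_cdm.exclusions
        assert set(excl.loc[excl["row_id"] == "L3", "reason"]) == {"rejected-patient"}

    def test_planted_inversions_all_rejected(self, defect_world, defect_cdm):
        planted = set(defect_world.manifest.defects["inverted_observation_period"])
        kept = set(defect_cdm.person["patient_source_id"])
        assert not planted & kept
        excl = defect_cdm.exclusions
        rejected = set(excl.loc[excl["source_table"] == "patient", "row_id"])
        assert rejected == planted


class TestPerson:
    def test_ethnicity_exclusively_from_hospital(self, micro):
        bundle, vocab = micro
        person = build_person(bundle, vocab).set_index("patient_source_id")
        # P1 has a primary-care ethnicity but no hospital record -> null
        assert pd.isna(person.loc["P1", "ethnicity_source_code"])
        # P3 has ETH1 in primary care but ETH2 in hospital -> hospital wins
        assert person.loc["P3", "ethnicity_source_code"] == "ETH2"
        assert person.loc["P3", "ethnicity_concept_id"] == 10

    def test_one_row_per_patient_even_without_events(self, micro):
        bundle, vocab = micro
        assert len(build_person(bundle, vocab)) == len(bundle.patient)

    def test_person_count_matches_generated_patients(self, clean_world, clean_cdm):
        assert len(clean_cdm.person) == len(clean_world.bundle.patient)


class TestVisits:
    def test_shared_consultation_yields_single_visit(self, micro_cdm):
        pc = micro_cdm.visit_occurrence
        assert (pc["visit_source_value"] == "C1").sum() == 1
        # both clinical rows point at that one visit
        cond = micro_cdm.condition_occurrence
        l1 = cond[cond["source_row_id"] == "L1"]
        assert l1["visit_occurrence_id"].notna().all()

    def test_undated_consultation_excluded(self, micro_cdm):
        assert "C2" not in set(micro_cdm.visit_occurrence["visit_source_value"])
        excl = micro_cdm.exclusions
        assert set(excl.loc[excl["row_id"] == "C2", "reason"]) == {"missing-date"}

    def test_planted_missing_dates_recovered(self, defect_world, defect_cdm):
        excl = defect_cdm.exclusions
        missing = excl[(excl["reason"] == "missing-date")
                       & (excl["source_table"].isin(["consultation", "hospital"]))]
        assert set(missing["row_id"]) \
            == set(defect_world.manifest.defects["missing_event_date"])

    def test_visit_ids_deterministic(self, micro):
        bundle, vocab = micro
        a = run_etl(bundle, vocab).cdm.visit_occurrence
        b = run_etl(bundle, vocab).cdm.visit_occurrence
        pd.testing.assert_frame_equal(a, b)


class TestRouting:
    def test_domain_routing(self, micro_cdm):
        cond = micro_cdm.condition_occurrence
        assert "L1" in set(cond["source_row_id"])          # condition domain
        obs = micro_cdm.observation
        assert "L2" in set(obs["source_row_id"])           # observation domain
        proc = micro_cdm.procedure_occurrence
        assert "H1:proc_1" in set(proc["source_row_id"])   # hospital procedure

    def test_orphan_reference_null_visit_and_flag(self, micro_cdm):
        drug = micro_cdm.drug_exposure.set_index("source_row_id")
        row = drug.loc["T1"]
        assert pd.isna(row["visit_occurrence_id"])
        assert row["invalid_visit_flag"] == 1
        assert row["visit_source_value"] == "CORPHAN"

    def test_broken_drug_chain_goes_to_ledger(self, micro_cdm):
        excl = micro_cdm.exclusions
        assert set(excl.loc[excl["row_id"] == "T2", "reason"]) == {"unmapped-code"}
        ledger = micro_cdm.code_mappings
        row = ledger[(ledger["source_code"] == "GBRK")]
        assert len(row) == 1 and pd.isna(row["target_concept_id"]).all()

    def test_unmapped_read_code_excluded_and_ledgered(self, micro_cdm):
        excl = micro_cdm.exclusions
        assert set(excl.loc[excl["row_id"] == "L4", "reason"]) == {"unmapped-code"}

    def test_zero_valued_entity_field_excluded(self, micro_cdm):
        excl = micro_cdm.exclusions
        assert set(excl.loc[excl["row_id"] == "E1:f2", "reason"]) \
            == {"zero-value-entity"}
        meas = micro_cdm.measurement
        assert list(meas["value_as_number"]) == [7.5]

    def test_death_causes_routed(self, micro_cdm):
        death = micro_cdm.death
        assert len(death) == 1
        assert death.iloc[0]["cause_concept_id"] == 3

    def test_defect_free_run_has_no_unmapped_or_excluded(self, clean_cdm):
        """Fully mapped vocabulary + no defects: every event lands in exactly
        one CDM table and the ledgers stay empty."""
        assert len(clean_cdm.exclusions) == 0
        assert clean_cdm.code_mappings["target_concept_id"].notna().all()

    def test_conservation_on_defect_run(self, defect_world, defect_cdm):
        """rows-in = unique emitted source rows + exclusion entries."""
        for table in ("clinical", "therapy"):
            emitted = set()
            for name in ("condition_occurrence", "procedure_occurrence",
                         "drug_exposure", "measurement", "observation"):
                frame = defect_cdm.tables[name]
                emitted |= set(frame.loc[frame["source_table"] == table,
                                         "source_row_id"])
            excl = defect_cdm.exclusions
            n_excluded = int((excl["source_table"] == table).sum())
            assert len(emitted) + n_excluded == len(defect_world.bundle.tables[table])


class TestDrugEras:
    def _exposure(self, rows):
        frame = pd.DataFrame(rows, columns=["person_id", "drug_concept_id",
                                            "drug_exposure_start_date"])
        frame["drug_exposure_start_date"] = pd.to_datetime(
            frame["drug_exposure_start_date"])
        base = empty_frame(CDM_SCHEMAS["drug_exposure"])
        for col in base.columns:
            if col not in frame.columns:
                frame[col] = pd.Series([None] * len(frame), dtype=base[col].dtype)
        frame["row_id"] = [str(i) for i in range(len(frame))]
        frame["invalid_visit_flag"] = 0
        frame["source_table"] = "therapy"
        frame["source_row_id"] = frame["row_id"]
        return coerce_frame(frame[base.columns.tolist()],
                            CDM_SCHEMAS["drug_exposure"])

    def test_single_exposure_single_default_duration_era(self):
        eras = derive_drug_eras(self._exposure([(1, 5, "2001-01-01")]),
                                gap_days=30, duration_days=30)
        assert len(eras) == 1
        assert eras.iloc[0]["drug_era_start_date"] == pd.Timestamp("2001-01-01")
        assert eras.iloc[0]["drug_era_end_date"] == pd.Timestamp("2001-01-31")

    def test_exposures_within_gap_merge(self):
        eras = derive_drug_eras(self._exposure(
            [(1, 5, "2001-01-01"), (1, 5, "2001-01-11")]), 30, 30)
        assert len(eras) == 1
        assert eras.iloc[0]["drug_exposure_count"] == 2
        assert eras.iloc[0]["drug_era_end_date"] == pd.Timestamp("2001-02-10")

    def test_exposures_beyond_gap_split(self):
        eras = derive_drug_eras(self._exposure(
            [(1, 5, "2001-01-01"), (1, 5, "2001-03-01")]), 30, 30)
        assert len(eras) == 2

    def test_matches_brute_force_interval_merging(self):
        """Randomized exposures against an independent interval-merge oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(60):
            n = int(rng.integers(1, 12))
            days = sorted(int(d) for d in rng.integers(0, 200, size=n))
            rows = [(1, 5, pd.Timestamp("2000-01-01") + pd.Timedelta(days=d))
                    for d in days]
            gap = int(rng.integers(1, 60))
            eras = derive_drug_eras(self._exposure(rows), gap, 30)
            # oracle: linear scan splitting whenever the start gap exceeds `gap`
            expected = []
            run = [days[0]]
            for d in days[1:]:
                if d - run[-1] <= gap:
                    run.append(d)
                else:
                    expected.append(run)
                    run = [d]
            expected.append(run)
            assert len(eras) == len(expected)
            for era, run in zip(eras.itertuples(index=False), expected):
                assert era.drug_era_start_date == \
                    pd.Timestamp("2000-01-01") + pd.Timedelta(days=run[0])
                assert era.drug_exposure_count == len(run)


def test_run_is_deterministic(clean_world):
    a = run_etl(clean_world.bundle, clean_world.vocab).cdm
    b = run_etl(clean_world.bundle, clean_world.vocab).cdm
    assert a == b


def test_conservation_lines_logged(micro, caplog):
    bundle, vocab = micro
    with caplog.at_level("INFO", logger="omoplink.etl"):
        run_etl(bundle, vocab)
    lines = [r.getMessage() for r in caplog.records
             if r.getMessage().startswith("conservation")]
    assert lines
    for line in lines:
        parts = dict(p.split("=") for p in line.split()[1:])
        assert parts["rows_in"] == parts["accounted"]
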