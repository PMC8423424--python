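"""Phenotype translation, execution on both representations, cohort rules."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from omoplink.etl import run_etl
from omoplink.phenotype import (CohortRules, PhenotypeDefinition,
                                PhenotypeResult, build_hf_cohort,
                                demographics_from_cdm, demographics_from_source,
                                find_patients_cdm, find_patients_source,
                                load_definitions, medication_flag,
                                read_definition, summarize_biomarker,
                                translate_codelist, write_definitions)
from omoplink.errors import ConfigurationError
from omoplink.vocab import Concept, VocabularyStore

from .conftest import STUDY_END, make_frame, micro_vocab


class TestTranslate:
    def test_many_to_one_collapse(self):
        v = VocabularyStore()
        v.add_concept(Concept(1, "SCT", "snomed", "condition", True))
        for code in ("RA", "RB", "RC"):
            v.add_edge(code, "read", 1)
        defn = PhenotypeDefinition("x", "condition", ("primary-care",),
                                   {"read": ["RA", "RB", "RC"]})
        concepts, unmapped = translate_codelist(defn, v)
        assert concepts == {1} and unmapped == []

    def test_unmapped_code_reported(self):
        v = micro_vocab()
        defn = PhenotypeDefinition("x", "condition", ("primary-care",),
                                   {"read": ["RA", "RUNMAPPED"]})
        concepts, unmapped = translate_codelist(defn, v)
        assert concepts == {1} and unmapped == ["RUNMAPPED"]

    def test_matches_brute_force_union(self, clean_world):
        """Random code lists against a direct resolve-and-union oracle."""
        rng = np.random.default_rng(5)
        vocab = clean_world.vocab
        all_read = sorted(vocab.source_terms["read"])
        for _ in range(40):
            codes = [all_read[i] for i in
                     rng.choice(len(all_read), size=int(rng.integers(1, 12)),
                                replace=False)]
            defn = PhenotypeDefinition("x", "condition", ("primary-care",),
                                       {"read": codes})
            concepts, unmapped = translate_codelist(defn, vocab)
            expected = set()
            expected_unmapped = []
            for c in codes:
                t = vocab.resolve(c, "read")
                if t:
                    expected.update(t)
                else:
                    expected_unmapped.append(c)
            assert concepts == expected
            assert unmapped == expected_unmapped


class TestSourceExecution:
    def test_membership_via_death_record_only(self):
        vocab = micro_vocab()
        bundle_tables = dict(
            patient=make_frame("patient", [
                dict(patient_id="P1", sex="F", year_of_birth=1950,
                     registration_date="2000-01-01", practice_id="PR1",
                     death_date="2005-05-05")]),
            practice=make_frame("practice", [
                dict(practice_id="PR1", up_to_standard_date="1999-01-01",
                     last_collection_date="2010-01-01")]),
            consultation=make_frame("consultation", []),
            clinical=make_frame("clinical", []),
            therapy=make_frame("therapy", []),
            test=make_frame("test", []),
            additional=make_frame("additional", []),
            hospital=make_frame("hospital", []),
            death=make_frame("death", [
                dict(patient_id="P1", death_date="2005-05-05",
                     underlying_cause="IA")]),
        )
        from omoplink.io import SourceBundle
        bundle = SourceBundle(**bundle_tables)
        defn = PhenotypeDefinition("hf", "condition",
                                   ("primary-care", "hospital", "death"),
                                   {"read": ["RA"], "icd10": ["IA"]})
        result = find_patients_source(defn, bundle)
        assert result.patient_ids == {"P1"}
        assert result.patients["P1"] == pd.Timestamp("2005-05-05")
        # without the death source the patient is invisible
        defn2 = PhenotypeDefinition("hf2", "condition", ("primary-care",),
                                    {"read": ["RA"], "icd10": ["IA"]})
        assert find_patients_source(defn2, bundle).patient_ids == set()

    def test_planted_membership_recovered_exactly(self, clean_world):
        for name in ("hf", "af", "copd", "t2dm", "ami", "ht", "cancer"):
            defn = clean_world.definitions[name]
            found = find_patients_source(defn, clean_world.bundle).patient_ids
            assert found == clean_world.manifest.members(name)


class TestCdmExecution:
    def test_untranslated_phenotype_errors(self, clean_cdm):
        defn = PhenotypeDefinition("x", "condition", ("primary-care",),
                                   {"read": ["RA"]})
        with pytest.raises(ConfigurationError):
            find_patients_cdm(defn, clean_cdm)

    def test_empty_cdm_gives_empty_result(self):
        from omoplink.io import CdmBundle
        defn = PhenotypeDefinition("x", "condition", ("primary-care",),
                                   {"read": ["RA"]}, concept_set={1})
        assert find_patients_cdm(defn, CdmBundle.empty()).patient_ids == set()

    def test_round_trip_source_equals_cdm(self, clean_world, clean_cdm):
        """Defect-free bundle + bijective vocabulary: identical patient sets
        for every phenotype, on both representations."""
        for name, defn in clean_world.definitions.items():
            translate_codelist(defn, clean_world.vocab)
            src = find_patients_source(defn, clean_world.bundle)
            cdm = find_patients_cdm(defn, clean_cdm)
            assert src.patient_ids == cdm.patient_ids, name

    def test_many_to_one_injection_grows_cdm_set(self, clean_world):
        from omoplink.synth import inject_many_to_one_mapping
        defn = clean_world.definitions["t2dm"]
        bundle, vocab, manifest = inject_many_to_one_mapping(
            clean_world.bundle, clean_world.vocab, clean_world.manifest,
            defn, n_codes=2, n_carriers=10, seed=21)
        cdm = run_etl(bundle, vocab).cdm
        translate_codelist(defn, vocab)
        src = find_patients_source(defn, bundle).patient_ids
        got = find_patients_cdm(defn, cdm).patient_ids
        assert got == src | set(manifest.incorrectly_mapped["t2dm"])


class TestCohortRules:
    def _demo(self, yob=1950, start="2000-01-01"):
        return pd.DataFrame(
            {"year_of_birth": [yob],
             "period_start": [pd.Timestamp(start)],
             "period_end": [pd.Timestamp("2012-01-01")]},
            index=pd.Index(["P1"], name="patient_id"))

    def _result(self, *dates):
        r = PhenotypeResult("hf")
        for d in dates:
            r._add("P1", pd.Timestamp(d))
        return r.finish()

    def test_index_is_first_event_on_or_after_entry_start(self):
        cohort = build_hf_cohort(self._result("1997-06-01", "2003-01-01"),
                                 self._demo())
        assert cohort.iloc[0]["index_date"] == pd.Timestamp("2003-01-01")
        assert cohort.iloc[0]["included"]

    def test_index_exactly_one_year_after_start_included(self):
        cohort = build_hf_cohort(self._result("2001-01-01"),
                                 self._demo(start="2000-01-01"))
        # 366 days (2000 is a leap year) >= 365: inside the boundary
        assert cohort.iloc[0]["included"]
        cohort2 = build_hf_cohort(self._result("2000-12-30"),  # 364 days
                                  self._demo(start="2000-01-01"))
        assert cohort2.iloc[0]["reason"] == "insufficient-prior-registration"

    def test_under_18_at_index_excluded(self):
        cohort = build_hf_cohort(self._result("2003-01-01"), self._demo(yob=1986))
        assert cohort.iloc[0]["reason"] == "under-age"
        cohort2 = build_hf_cohort(self._result("2004-01-01"), self._demo(yob=1986))
        assert cohort2.iloc[0]["included"]

    def test_matches_brute_force_rule_evaluation(self, clean_world, clean_cdm):
        """Cohort on generated data against an explicit per-patient check."""
        defn = clean_world.definitions["hf"]
        translate_codelist(defn, clean_world.vocab)
        result = find_patients_source(defn, clean_world.bundle)
        demo = demographics_from_source(clean_world.bundle, STUDY_END)
        rules = CohortRules()
        cohort = build_hf_cohort(result, demo, rules).set_index("patient_id")
        entry = pd.Timestamp(rules.entry_start)
        for pid in result.patients:
            dates = [d for d in result.dates.get(pid, []) if d >= entry]
            expect_included = False
            if dates and pid in demo.index:
                idx = dates[0]
                age = idx.year - int(demo.loc[pid, "year_of_birth"])
                prior = (idx - demo.loc[pid, "period_start"]).days
                expect_included = age >= 18 and prior >= 365
            assert bool(cohort.loc[pid, "included"]) == expect_included, pid

    def test_source_and_cdm_demographics_agree(self, clean_world, clean_cdm):
        src = demographics_from_source(clean_world.bundle, STUDY_END)
        cdm = demographics_from_cdm(clean_cdm)
        joined = src.join(cdm, lsuffix="_s", rsuffix="_c", how="inner")
        assert len(joined) == len(src) == len(cdm)
        assert (joined["period_start_s"] == joined["period_start_c"]).all()
        assert (joined["period_end_s"] == joined["period_end_c"]).all()


class TestSummaries:
    def test_simple_biomarker_stats(self):
        r = PhenotypeResult("bmi")
        for i, v in enumerate([1.0, 2.0, 3.0]):
            r.patients[f"P{i}"] = pd.Timestamp("2001-01-01")
            r.records[f"P{i}"] = [(pd.Timestamp("2001-06-01"), v)]
        cohort = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(3)],
            "index_date": [pd.Timestamp("2001-01-01")] * 3,
            "follow_up_end": [pd.Timestamp("2010-01-01")] * 3,
            "included": [True] * 3, "reason": ["included"] * 3})
        s = summarize_biomarker(r, cohort)
        assert (s.n, s.median, s.mean) == (3, 2.0, 2.0)

    def test_no_values_gives_empty_summary(self):
        cohort = pd.DataFrame({"patient_id": [], "index_date": [],
                               "follow_up_end": [], "included": [], "reason": []})
        s = summarize_biomarker(PhenotypeResult("x"), cohort)
        assert s.n == 0 and s.median is None

    def test_stats_match_numpy_oracle(self):
        """First-on-or-after-index selection and moments vs direct numpy."""
        rng = np.random.default_rng(77)
        r = PhenotypeResult("x")
        cohort_rows = []
        expected_values = []
        for i in range(80):
            pid = f"P{i}"
            index = pd.Timestamp("2001-01-01") + pd.Timedelta(days=int(rng.integers(0, 900)))
            recs = sorted(
                (pd.Timestamp("2000-06-01") + pd.Timedelta(days=int(rng.integers(0, 2000))),
                 float(rng.normal(100, 15))) for _ in range(int(rng.integers(0, 5))))
            r.records[pid] = recs
            cohort_rows.append((pid, index, pd.Timestamp("2009-01-01"), True, "included"))
            after = [v for d, v in recs if index <= d <= pd.Timestamp("2009-01-01")]
            if after:
                expected_values.append(after[0])
        cohort = pd.DataFrame(cohort_rows, columns=["patient_id", "index_date",
                                                    "follow_up_end", "included",
                                                    "reason"])
        s = summarize_biomarker(r, cohort)
        arr = np.array(expected_values)
        assert s.n == len(arr)
        assert abs(s.median - np.median(arr)) < 1e-9
        assert abs(s.mean - arr.mean()) < 1e-9
        assert abs(s.sd - arr.std(ddof=1)) < 1e-9
        assert abs(s.iqr - (np.percentile(arr, 75) - np.percentile(arr, 25))) < 1e-9

    def test_medication_flag_boundaries(self):
        cohort = pd.DataFrame({
            "patient_id": ["P0", "P1"], "index_date": [pd.Timestamp("2001-01-01")] * 2,
            "follow_up_end": [pd.Timestamp("2010-01-01")] * 2,
            "included": [True, True], "reason": ["included"] * 2})
        empty = PhenotypeResult("m")
        assert medication_flag(empty, cohort) == 0.0
        full = PhenotypeResult("m")
        full.patients = {"P0": None, "P1": None}
        assert medication_flag(full, cohort) == 100.0

    def test_medication_flag_recovers_planted_fraction(self, clean_world):
        """Planted exposure fraction within the cohort is reproduced exactly."""
        defn_hf = clean_world.definitions["hf"]
        translate_codelist(defn_hf, clean_world.vocab)
        hf = find_patients_source(defn_hf, clean_world.bundle)
        demo = demographics_from_source(clean_world.bundle, STUDY_END)
        cohort = build_hf_cohort(hf, demo)
        included = set(cohort.loc[cohort["included"], "patient_id"])
        for med in ("loop_diuretics", "ace_inhibitors", "beta_blockers"):
            result = find_patients_source(clean_world.definitions[med],
                                          clean_world.bundle)
            expected = 100 * len(included & clean_world.manifest.members(med)) \
                / len(included)
            got = medication_flag(result, cohort)
            assert abs(got - expected) < 0.1  # within 1-decimal rounding


def test_definition_file_round_trip(tmp_path, clean_world):
    write_definitions(clean_world.definitions, tmp_path)
    back = load_definitions(tmp_path)
    assert set(back) == set(clean_world.definitions)
    for name, defn in clean_world.definitions.items():
        assert back[name].codelists == defn.codelists
        assert back[name].sources == defn.sources
        assert back[name].kind == defn.kind
        assert back[name].categories == defn.categories


def test_definition_requires_nonempty_codelist():
    with pytest.raises(ConfigurationError):
        PhenotypeDefinition("x", "condition", ("primary-care",), {"read": []})
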