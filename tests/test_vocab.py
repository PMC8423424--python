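"""Concept resolution, drug chains, entity-row expansion and coverage."""

import numpy as np
import pandas as pd
import pytest

from omoplink.errors import VocabularyLookupError
from omoplink.vocab import Concept, EntityField, VocabularyStore

from .conftest import micro_vocab


@pytest.fixture()
def store():
    return micro_vocab()


class TestResolve:
    def test_unmapped_code_resolves_to_empty_list(self, store):
        assert store.resolve("RUNMAPPED", "read") == []

    def test_unknown_vocabulary_raises(self, store):
        with pytest.raises(VocabularyLookupError):
            store.resolve("RA", "no-such-vocab")

    def test_many_to_one_codes_share_target(self, store):
        store.add_edge("RA2", "read", 1)
        assert store.resolve("RA", "read") == store.resolve("RA2", "read") == [1]

    def test_one_to_many_targets_ascending(self, store):
        store.add_concept(Concept(99, "SCT-Z", "snomed", "condition", True))
        store.add_edge("RMULTI", "read", 99)
        store.add_edge("RMULTI", "read", 1)
        assert store.resolve("RMULTI", "read") == [1, 99]

    def test_mapped_count_matches_edge_enumeration(self):
        """10 codes, 7 with edges: exactly 7 non-empty resolutions."""
        v = VocabularyStore()
        v.add_concept(Concept(1, "C1", "snomed", "condition", True))
        for i in range(10):
            code = f"R{i}"
            if i < 7:
                v.add_edge(code, "read", 1)
            else:
                v.register_term("read", code)
        resolved = [v.resolve(f"R{i}", "read") for i in range(10)]
        assert sum(1 for r in resolved if r) == 7
        assert v.mapped_codes("read") == {f"R{i}" for i in range(7)}


class TestDrugChain:
    def test_complete_chain_resolves(self, store):
        assert store.resolve_drug("GA") == 5

    def test_broken_second_hop_yields_none(self, store):
        # hop 1 exists (GBRK -> dictionary) but the dictionary entry has no
        # standard-drug mapping: the dominant prescription-mapping failure
        assert store.resolve_drug("GBRK") is None

    def test_unknown_code_yields_none(self, store):
        assert store.resolve_drug("G404") is None

    def test_chain_count_matches_construction(self):
        v = VocabularyStore()
        complete, total = 4, 9
        for i in range(total):
            dmd = Concept(100 + i, f"D{i}", "dmd", "drug", False)
            v.add_concept(dmd)
            v.add_edge(f"G{i}", "gemscript", 100 + i, relationship="translates-to")
            if i < complete:
                v.add_concept(Concept(200 + i, f"RX{i}", "rxnorm", "drug", True))
                v.add_edge(f"D{i}", "dmd", 200 + i)
        assert len(v.mapped_codes("gemscript")) == complete


class TestEntityRow:
    def test_two_populated_mapped_fields_two_candidates(self, store):
        res = store.resolve_entity_row(9, ["7.5", "88", None, None,
                                           None, None, None, None], "U1")
        assert len(res.candidates) == 2
        assert res.unmapped_fields == [] and res.excluded_fields == []
        assert all(c.unit_concept_id == 8 for c in res.candidates)

    def test_all_fields_empty_nothing_counted(self, store):
        res = store.resolve_entity_row(9, [None] * 8, None)
        assert (res.candidates, res.unmapped_fields, res.excluded_fields) == ([], [], [])

    def test_ignore_zero_field_with_zero_is_excluded(self, store):
        res = store.resolve_entity_row(9, [None, "0", None, None,
                                           None, None, None, None], None)
        assert res.candidates == []
        assert res.excluded_fields == [2]

    def test_unmapped_field_counted(self, store):
        store.entity_map[(9, 3)] = EntityField(None, "coded")
        res = store.resolve_entity_row(9, [None, None, "X", None,
                                           None, None, None, None], None)
        assert res.candidates == [] and res.unmapped_fields == [3]

    def test_unknown_entity_type_all_populated_fields_unmapped(self, store):
        res = store.resolve_entity_row(404, ["1", "2", None, None,
                                             None, None, None, None], None)
        assert res.unmapped_fields == [1, 2]

    def test_missing_unit_kept_with_null_unit_concept(self, store):
        res = store.resolve_entity_row(9, ["7.5"] + [None] * 7, "UNOSUCH")
        assert len(res.candidates) == 1
        assert res.candidates[0].unit_concept_id is None


class TestCoverage:
    def _vocab(self):
        v = VocabularyStore()
        v.add_concept(Concept(1, "T", "snomed", "condition", True))
        for i in range(8):
            v.add_edge(f"K{i}", "read", 1)
        v.register_term("read", "K8")
        v.register_term("read", "K9")
        return v

    def test_hand_enumerated_example(self):
        """10 terms / 8 mapped; 5 used of which 4 mapped; 100 events of which
        90 on mapped codes and 2 excluded -- columns computed by counting."""
        v = self._vocab()
        codes = (["K0"] * 30 + ["K1"] * 30 + ["K2"] * 20 + ["K3"] * 10
                 + ["K8"] * 10)  # K8 is the used-but-unmapped term
        excluded = [False] * len(codes)
        excluded[0] = excluded[31] = True  # two excluded events on mapped codes
        events = pd.DataFrame({"code": pd.Series(codes, dtype="string"),
                               "excluded": excluded})
        row = v.coverage(events, "read")
        assert row.total_terms == 10
        assert row.total_mapped_terms_pct == 80.0
        assert row.used_terms == 5
        assert row.used_mapped_terms_pct == 80.0
        assert row.total_events == 100
        assert row.excluded_events_pct == 2.0
        # mapped events = 90 on mapped codes minus 2 excluded = 88
        assert row.mapped_events_pct == 88.0

    def test_all_used_terms_mapped_no_exclusions(self):
        v = self._vocab()
        events = pd.DataFrame({"code": pd.Series(["K0", "K1"], dtype="string"),
                               "excluded": [False, False]})
        row = v.coverage(events, "read")
        assert row.used_mapped_terms_pct == 100.0
        assert row.mapped_events_pct == 100.0

    def test_zero_events_reports_empty_flag(self):
        v = self._vocab()
        events = pd.DataFrame({"code": pd.Series([], dtype="string"),
                               "excluded": pd.Series([], dtype=bool)})
        row = v.coverage(events, "read")
        assert row.empty and row.total_events == 0
        assert row.mapped_events_pct == 0.0

    def test_event_conservation_on_random_inputs(self):
        """mapped + unmapped + excluded = total for arbitrary event mixes."""
        rng = np.random.default_rng(1234)
        v = self._vocab()
        terms = [f"K{i}" for i in range(10)]
        for _ in range(50):
            n = int(rng.integers(1, 60))
            codes = [terms[int(rng.integers(0, 10))] for _ in range(n)]
            excluded = rng.random(n) < 0.2
            events = pd.DataFrame({"code": pd.Series(codes, dtype="string"),
                                   "excluded": excluded})
            row = v.coverage(events, "read")  # asserts conservation internally
            assert row.total_events == n

    def test_adding_edge_never_decreases_coverage(self):
        """Monotonicity: a new mapping edge can only help every percentage."""
        rng = np.random.default_rng(99)
        terms = [f"K{i}" for i in range(10)]
        for _ in range(30):
            v = self._vocab()
            n = int(rng.integers(5, 50))
            codes = [terms[int(rng.integers(0, 10))] for _ in range(n)]
            events = pd.DataFrame({"code": pd.Series(codes, dtype="string"),
                                   "excluded": [False] * n})
            before = v.coverage(events, "read")
            v.add_edge("K8", "read", 1)
            after = v.coverage(events, "read")
            assert after.total_mapped_terms_pct >= before.total_mapped_terms_pct
            assert after.used_mapped_terms_pct >= before.used_mapped_terms_pct
            assert after.mapped_events_pct >= before.mapped_events_pct
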