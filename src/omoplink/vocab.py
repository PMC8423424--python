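"""Concept store, terminology mapping edges and coverage accounting.

The store holds three kinds of mapping knowledge:

- ``maps-to`` edges from a (vocabulary, code) pair to standard concepts —
  the ordinary one-hop route used for diagnosis/procedure/observation codes
  (many-to-one and one-to-many are both legal);
- ``translates-to`` edges for the first hop of the two-hop prescription
  chain (prescription code -> drug dictionary entry); the second hop is an
  ordinary ``maps-to`` edge from the dictionary entry's own code. A broken
  second hop leaves the prescription unmapped — the dominant drug-mapping
  failure mode in UK primary-care extracts;
- an entity-field map turning wide laboratory/examination rows (an entity
  type with up to eight value slots) into per-field measurement concepts,
  with ``ignore-zero`` semantics for fields where "0" denotes
  "value not entered".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .errors import VocabularyLookupError
from .rounding import pct
from .schemas import N_ENTITY_FIELDS, VOCAB_SCHEMAS

MAPS_TO = "maps-to"
TRANSLATES_TO = "translates-to"

DOMAINS = ("condition", "procedure", "drug", "measurement", "observation",
           "unit", "death-cause")


@dataclass(frozen=True)
class Concept:
    concept_id: int
    code: str
    vocabulary: str
    domain: str | None
    standard: bool


@dataclass(frozen=True)
class EntityField:
    target_concept_id: int | None
    semantics: str  # numeric | coded | ignore-zero


@dataclass
class MeasurementCandidate:
    field_index: int
    concept_id: int
    value: str
    unit_concept_id: int | None
    unit_code: str | None


@dataclass
class EntityRowResult:
    candidates: list[MeasurementCandidate]
    unmapped_fields: list[int]
    excluded_fields: list[int]


@dataclass
class CoverageRow:
    """One vocabulary's row of the mapping-coverage table."""

    vocabulary: str
    total_terms: int
    total_mapped_terms_pct: float
    used_terms: int
    used_mapped_terms_pct: float
    total_events: int
    excluded_events_pct: float
    mapped_events_pct: float
    empty: bool = False

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class VocabularyStore:
    """Concepts plus directed mapping edges between terminologies."""

    def __init__(self):
        self.concepts: dict[int, Concept] = {}
        self._edges: dict[tuple[str, str, str], list[int]] = {}
        self.entity_map: dict[tuple[int, int], EntityField] = {}
        self.unit_map: dict[str, int | None] = {}
        self.source_terms: dict[str, set[str]] = {}
        #: vocabulary whose codes resolve through the two-hop drug chain
        self.drug_vocabulary = "gemscript"
        self.drug_intermediate = "dmd"

    # -- construction ------------------------------------------------------
    def add_concept(self, concept: Concept) -> None:
        if concept.concept_id in self.concepts:
            raise VocabularyLookupError(f"duplicate concept id {concept.concept_id}")
        if concept.standard and concept.domain is None:
            raise VocabularyLookupError(
                f"standard concept {concept.concept_id} has no domain")
        self.concepts[concept.concept_id] = concept

    def add_edge(self, code: str, vocabulary: str, target_concept_id: int,
                 relationship: str = MAPS_TO) -> None:
        if target_concept_id not in self.concepts:
            raise VocabularyLookupError(
                f"edge target {target_concept_id} not in concept table")
        key = (relationship, vocabulary, code)
        targets = self._edges.setdefault(key, [])
        if target_concept_id not in targets:
            targets.append(target_concept_id)
            targets.sort()
        self.register_term(vocabulary, code)

    def register_term(self, vocabulary: str, code: str) -> None:
        self.source_terms.setdefault(vocabulary, set()).add(code)

    @property
    def vocabularies(self) -> set[str]:
        return set(self.source_terms)

    # -- resolution --------------------------------------------------------
    def resolve(self, code: str, vocabulary: str) -> list[int]:
        """Standard-concept ids for a source code, ascending; [] if unmapped."""
        if vocabulary not in self.vocabularies:
            raise VocabularyLookupError(f"unknown vocabulary {vocabulary!r}")
        return list(self._edges.get((MAPS_TO, vocabulary, code), []))

    def resolve_drug(self, drug_code: str) -> int | None:
        """Two-hop prescription resolution; None unless BOTH hops exist."""
        hop1 = self._edges.get((TRANSLATES_TO, self.drug_vocabulary, drug_code), [])
        for intermediate_id in hop1:
            intermediate = self.concepts[intermediate_id]
            hop2 = self._edges.get(
                (MAPS_TO, self.drug_intermediate, intermediate.code), [])
            if hop2:
                return hop2[0]
        return None

    def resolve_entity_row(self, entity_type_id: int, values, unit_code: str | None
                           ) -> EntityRowResult:
        """Wide-to-long expansion of one test/additional row.

        One measurement candidate per populated, mapped field. Populated
        fields without a usable mapping count as unmapped; ignore-zero
        fields holding "0" count as excluded. Empty fields count as nothing.
        """
        result = EntityRowResult([], [], [])
        known = any(k[0] == entity_type_id for k in self.entity_map)
        unit_concept = self.unit_map.get(unit_code) if unit_code else None
        for idx in range(1, N_ENTITY_FIELDS + 1):
            value = values[idx - 1]
            if value is None or (isinstance(value, float) and pd.isna(value)) or value is pd.NA:
                continue
            value = str(value)
            if value == "":
                continue
            if not known:
                result.unmapped_fields.append(idx)
                continue
            entry = self.entity_map.get((entity_type_id, idx))
            if entry is None or entry.target_concept_id is None:
                result.unmapped_fields.append(idx)
                continue
            if entry.semantics == "ignore-zero" and value == "0":
                result.excluded_fields.append(idx)
                continue
            result.candidates.append(MeasurementCandidate(
                idx, entry.target_concept_id, value, unit_concept, unit_code))
        return result

    def mapped_codes(self, vocabulary: str) -> set[str]:
        """Codes of *vocabulary* with a complete resolution path."""
        terms = self.source_terms.get(vocabulary, set())
        if vocabulary == self.drug_vocabulary:
            return {c for c in terms if self.resolve_drug(c) is not None}
        return {c for c in terms if self.resolve(c, vocabulary)}

    def domain_of(self, concept_id: int) -> str | None:
        return self.concepts[concept_id].domain

    # -- coverage ----------------------------------------------------------
    def coverage(self, events: pd.DataFrame, vocabulary: str,
                 places: int = 2, mode: str = "truncate") -> CoverageRow:
        """Coverage-table row for one vocabulary.

        *events* needs columns ``code`` and boolean ``excluded`` (dropped for
        a non-mapping reason: missing date, rejected patient, zero-valued
        entity field). Conservation — mapped + unmapped + excluded = total —
        holds by construction and is asserted.
        """
        if vocabulary not in self.vocabularies:
            raise VocabularyLookupError(f"unknown vocabulary {vocabulary!r}")
        terms = self.source_terms[vocabulary]
        mapped = self.mapped_codes(vocabulary)
        total_terms = len(terms)
        total_mapped_pct = pct(len(mapped), total_terms, places, mode) if total_terms else 0.0

        codes = events["code"].astype("string")
        used = set(codes.dropna())
        used_mapped = used & mapped
        total_events = len(events)
        if total_events == 0:
            return CoverageRow(vocabulary, total_terms, total_mapped_pct,
                               len(used),
                               pct(len(used_mapped), len(used), places, mode) if used else 0.0,
                               0, 0.0, 0.0, empty=True)
        excluded = events["excluded"].astype(bool)
        is_mapped = codes.isin(sorted(mapped)) & ~excluded
        n_excluded = int(excluded.sum())
        n_mapped = int(is_mapped.sum())
        n_unmapped = total_events - n_excluded - n_mapped
        assert n_mapped + n_unmapped + n_excluded == total_events
        return CoverageRow(
            vocabulary, total_terms, total_mapped_pct,
            len(used),
            pct(len(used_mapped), len(used), places, mode) if used else 0.0,
            total_events,
            pct(n_excluded, total_events, places, mode),
            pct(n_mapped, total_events, places, mode),
        )

    # -- persistence -------------------------------------------------------
    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        concepts = pd.DataFrame(
            [(str(c.concept_id), c.code, c.vocabulary, c.domain, int(c.standard))
             for c in sorted(self.concepts.values(), key=lambda c: c.concept_id)],
            columns=["concept_id", "code", "vocabulary", "domain", "standard"])
        edges = pd.DataFrame(
            [(str(i), code, voc, tgt, rel)
             for i, ((rel, voc, code), tgts) in enumerate(sorted(self._edges.items()))
             for tgt in tgts],
            columns=["edge_id", "source_code", "source_vocabulary",
                     "target_concept_id", "relationship"])
        edges["edge_id"] = [str(i) for i in range(len(edges))]
        entity = pd.DataFrame(
            [(str(i), et, fi,
              None if ef.target_concept_id is None else ef.target_concept_id,
              ef.semantics)
             for i, ((et, fi), ef) in enumerate(sorted(self.entity_map.items()))],
            columns=["map_id", "entity_type_id", "field_index",
                     "target_concept_id", "semantics"])
        units = pd.DataFrame(
            [(code, tgt) for code, tgt in sorted(self.unit_map.items())],
            columns=["unit_code", "target_concept_id"])
        terms = pd.DataFrame(
            [(str(i), voc, code)
             for i, (voc, code) in enumerate(
                 sorted((v, c) for v, cs in self.source_terms.items() for c in cs))],
            columns=["term_id", "vocabulary", "code"])
        for name, frame in [("concept", concepts), ("mapping_edge", edges),
                            ("entity_field_map", entity), ("unit_map", units),
                            ("source_term", terms)]:
            schema = VOCAB_SCHEMAS[name]
            frame = io.coerce_frame(frame, schema) if len(frame) else io.empty_frame(schema)
            io.write_table(frame, directory / f"{name}.csv", schema)

    @classmethod
    def read(cls, directory: str | Path) -> "VocabularyStore":
        directory = Path(directory)
        store = cls()
        concepts = io.read_table(directory / "concept.csv", VOCAB_SCHEMAS["concept"]).frame
        for r in concepts.itertuples(index=False):
            store.add_concept(Concept(int(r.concept_id), str(r.code), str(r.vocabulary),
                                      None if pd.isna(r.domain) else str(r.domain),
                                      bool(r.standard)))
        edges = io.read_table(directory / "mapping_edge.csv",
                              VOCAB_SCHEMAS["mapping_edge"]).frame
        for r in edges.itertuples(index=False):
            store.add_edge(str(r.source_code), str(r.source_vocabulary),
                           int(r.target_concept_id), str(r.relationship))
        entity = io.read_table(directory / "entity_field_map.csv",
                               VOCAB_SCHEMAS["entity_field_map"]).frame
        for r in entity.itertuples(index=False):
            tgt = None if pd.isna(r.target_concept_id) else int(r.target_concept_id)
            store.entity_map[(int(r.entity_type_id), int(r.field_index))] = \
                EntityField(tgt, str(r.semantics))
        units = io.read_table(directory / "unit_map.csv", VOCAB_SCHEMAS["unit_map"]).frame
        for r in units.itertuples(index=False):
            store.unit_map[str(r.unit_code)] = \
                None if pd.isna(r.target_concept_id) else int(r.target_concept_id)
        terms = io.read_table(directory / "source_term.csv",
                              VOCAB_SCHEMAS["source_term"]).frame
        for r in terms.itertuples(index=False):
            store.register_term(str(r.vocabulary), str(r.code))
        return store
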