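"""Multi-source entity registry with weighted name resolution.

Public biological databases disagree about names: two databases may call the
same gene differently (resolvable by a third database that knows both names),
and two different genes may share a synonym (reported, never auto-merged).
The registry accumulates (source, entity, name) assertions, weights every
name by the number of distinct sources supporting it, flags conflicts, and
answers simple / keyword / wildcard / multi-word searches over names and
property text.
"""

from __future__ import annotations

import fnmatch
import itertools
from dataclasses import dataclass, field
from enum import Enum

from scipy.stats import binom


class EntityType(str, Enum):
    gene = "gene"
    protein = "protein"
    TF = "TF"
    pathway = "pathway"
    experiment = "experiment"
    publication = "publication"
    other = "other"


def _norm(name: str) -> str:
    """Canonical form used for matching: case-insensitive, trimmed."""
    return name.strip().lower()


@dataclass(frozen=True)
class SourceRecord:
    """One source database's assertion about an entity and its names."""

    source_id: str
    entity_key: str
    names: tuple[str, ...]
    organism: str
    entity_type: str = "gene"

    def __post_init__(self):
        if not self.source_id:
            raise ValueError("source_id must be non-empty")
        if not self.names:
            raise ValueError(f"record {self.source_id}:{self.entity_key} has no names")
        object.__setattr__(self, "names", tuple(self.names))


@dataclass(frozen=True)
class NameWeight:
    """A name with its support: the number of distinct sources asserting it."""

    name: str
    support_count: int

    def __post_init__(self):
        if self.support_count < 1:
            raise ValueError("support_count must be >= 1")


@dataclass
class EntityRecord:
    canonical_id: str
    organism: str
    entity_type: str
    name_weights: list[NameWeight] = field(default_factory=list)
    properties: dict[str, str] = field(default_factory=dict)

    @property
    def names(self) -> list[str]:
        return [nw.name for nw in self.name_weights]


@dataclass(frozen=True)
class ConflictReport:
    """A detected naming conflict.

    kind 'shared_name': one name asserted for >= 2 distinct entities.
    kind 'divergent_names': one entity for which two sources assert disjoint
    name sets (the same gene named differently with no shared synonym).
    """

    kind: str  # shared_name | divergent_names
    name_or_entity: str
    implicated: tuple[str, ...]

    def __post_init__(self):
        if len(self.implicated) < 2:
            raise ValueError("a conflict implicates at least two parties")


class NotFoundError(KeyError):
    pass


@dataclass
class SearchResult:
    """Ranked hits; multiword mode also carries the OR-only block."""

    and_results: list[EntityRecord]
    or_results: list[EntityRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.and_results)

    def __len__(self):
        return len(self.and_results)


class EntityRegistry:
    """Accumulates source assertions and resolves names to entities.

    Entity resolution on registration: a record merges into an existing
    entity when it shares at least one (normalized) name with it within the
    same organism and entity type; otherwise a new entity is created. Each
    (source, entity, name) assertion is counted once, so re-registering a
    source is a no-op for support counts.
    """

    def __init__(self):
        self.entities: dict[str, EntityRecord] = {}
        # (source_id, canonical_id, normalized name) seen assertions
        self._assertions: set[tuple[str, str, str]] = set()
        # normalized name -> {canonical_id}
        self._name_to_entities: dict[str, set[str]] = {}
        # (canonical_id, normalized name) -> {source_id}
        self._support: dict[tuple[str, str], set[str]] = {}
        # (canonical_id, norm name) -> display name first seen
        self._display: dict[tuple[str, str], str] = {}
        # per-entity, per-source asserted normalized-name sets (divergence check)
        self._entity_source_names: dict[str, dict[str, set[str]]] = {}
        self._counter = itertools.count(1)

    # -- registration ------------------------------------------------------

    def register_source(self, records: list[SourceRecord]) -> dict:
        """Ingest one batch of source assertions; returns a delta summary."""
        new_entities = 0
        new_assertions = 0
        for rec in records:
            ent = self._resolve_or_create(rec)
            if ent is None:
                continue
            canonical_id, created = ent
            new_entities += created
            for raw in rec.names:
                key = _norm(raw)
                if not key:
                    continue
                assertion = (rec.source_id, canonical_id, key)
                if assertion in self._assertions:
                    continue
                self._assertions.add(assertion)
                new_assertions += 1
                self._support.setdefault((canonical_id, key), set()).add(rec.source_id)
                self._name_to_entities.setdefault(key, set()).add(canonical_id)
                self._display.setdefault((canonical_id, key), raw.strip())
                self._entity_source_names.setdefault(canonical_id, {}) \
                    .setdefault(rec.source_id, set()).add(key)
            self._refresh_weights(canonical_id)
        return {"new_entities": new_entities, "new_assertions": new_assertions}

    def _resolve_or_create(self, rec: SourceRecord) -> tuple[str, bool] | None:
        keys = [_norm(n) for n in rec.names if _norm(n)]
        if not keys:
            return None
        for key in keys:
            for cid in sorted(self._name_to_entities.get(key, ())):
                ent = self.entities[cid]
                if ent.organism == rec.organism and ent.entity_type == rec.entity_type:
                    return cid, False
        cid = f"BN{next(self._counter):06d}"
        if cid in self.entities:  # pragma: no cover - counter is monotone
            raise ValueError(f"canonical_id collision: {cid}")
        self.entities[cid] = EntityRecord(
            canonical_id=cid, organism=rec.organism, entity_type=rec.entity_type
        )
        return cid, True

    def _refresh_weights(self, canonical_id: str) -> None:
        ent = self.entities[canonical_id]
        weights = []
        for (cid, key), sources in self._support.items():
            if cid == canonical_id:
                weights.append(NameWeight(self._display[(cid, key)], len(sources)))
        ent.name_weights = self._order_names(canonical_id, weights)

    # -- ranking -----------------------------------------------------------

    def _shared_name_keys(self) -> set[str]:
        return {k for k, ents in self._name_to_entities.items() if len(ents) > 1}

    def _order_names(self, canonical_id: str, weights: list[NameWeight]) -> list[NameWeight]:
        conflicted = self._shared_name_keys()
        # conflicted names sink below non-conflicted names of equal support
        return sorted(
            weights,
            key=lambda nw: (-nw.support_count, _norm(nw.name) in conflicted, _norm(nw.name)),
        )

    def rank_names(self, entity: str | EntityRecord) -> list[NameWeight]:
        """Names of an entity, descending by source support.

        Ties break by the conflict flag (shared names sink) then
        case-insensitive lexicographic order, so the ranking is deterministic.
        """
        cid = entity.canonical_id if isinstance(entity, EntityRecord) else entity
        if cid not in self.entities:
            raise NotFoundError(f"unknown entity: {cid}")
        self._refresh_weights(cid)
        return list(self.entities[cid].name_weights)

    # -- conflicts ---------------------------------------------------------

    def conflicts(self) -> list[ConflictReport]:
        """All shared-name and divergent-name conflicts currently present."""
        out: list[ConflictReport] = []
        for key in sorted(self._shared_name_keys()):
            ents = tuple(sorted(self._name_to_entities[key]))
            out.append(ConflictReport("shared_name", key, ents))
        for cid in sorted(self._entity_source_names):
            per_source = self._entity_source_names[cid]
            if len(per_source) < 2:
                continue
            divergent_sources: set[str] = set()
            for (s1, n1), (s2, n2) in itertools.combinations(
                sorted(per_source.items()), 2
            ):
                if not (n1 & n2):
                    divergent_sources.update((s1, s2))
            if divergent_sources:
                out.append(
                    ConflictReport("divergent_names", cid, tuple(sorted(divergent_sources)))
                )
        return out

    # -- search ------------------------------------------------------------

    def _entity_rank_key(self, ent: EntityRecord):
        best = max((nw.support_count for nw in ent.name_weights), default=0)
        return (-best, ent.canonical_id)

    def _ranked(self, cids: set[str]) -> list[EntityRecord]:
        return sorted((self.entities[c] for c in cids), key=self._entity_rank_key)

    def _organism_ok(self, cid: str, organism: str | None) -> bool:
        return organism is None or self.entities[cid].organism == organism

    def _match_simple(self, token: str, organism) -> set[str]:
        key = _norm(token)
        return {c for c in self._name_to_entities.get(key, ()) if self._organism_ok(c, organism)}

    def _match_keyword(self, token: str, organism) -> set[str]:
        key = _norm(token)
        hits: set[str] = set()
        for name_key, cids in self._name_to_entities.items():
            if key in name_key:
                hits.update(c for c in cids if self._organism_ok(c, organism))
        for cid, ent in self.entities.items():
            if not self._organism_ok(cid, organism):
                continue
            for k, v in ent.properties.items():
                if key in _norm(str(k)) or key in _norm(str(v)):
                    hits.add(cid)
                    break
        return hits

    def _match_wildcard(self, token: str, organism) -> set[str]:
        pattern = _norm(token)
        if pattern.count("[") != pattern.count("]"):
            raise ValueError(f"malformed glob pattern: {token!r}")
        if not any(ch in pattern for ch in "*?["):
            pattern += "*"  # bare prefix behaves as prefix search
        hits: set[str] = set()
        for name_key, cids in self._name_to_entities.items():
            if fnmatch.fnmatchcase(name_key, pattern):
                hits.update(c for c in cids if self._organism_ok(c, organism))
        return hits

    def search(
        self,
        query: str,
        mode: str = "simple",
        organism_filter: str | None = None,
    ) -> SearchResult:
        """Search the registry.

        simple    — exact name match over a comma-separated list (comma = OR)
        keyword   — substring match over names and property values
        wildcard  — glob match ('neurodeg*'); a bare token is a prefix
        multiword — space-separated terms; the AND result set is returned
                    first, followed by the OR-only result set
        """
        if not query or not query.strip():
            raise ValueError("query must be non-empty")
        tokens = [t.strip() for t in query.split(",") if t.strip()]
        if mode == "simple":
            hits = set().union(*(self._match_simple(t, organism_filter) for t in tokens))
            return SearchResult(self._ranked(hits))
        if mode == "keyword":
            hits = set().union(*(self._match_keyword(t, organism_filter) for t in tokens))
            return SearchResult(self._ranked(hits))
        if mode == "wildcard":
            hits = set().union(*(self._match_wildcard(t, organism_filter) for t in tokens))
            return SearchResult(self._ranked(hits))
        if mode == "multiword":
            and_hits: set[str] | None = None
            or_hits: set[str] = set()
            for comma_block in tokens:
                block_and: set[str] | None = None
                for word in comma_block.split():
                    word_hits = self._match_keyword(word, organism_filter)
                    or_hits |= word_hits
                    block_and = word_hits if block_and is None else (block_and & word_hits)
                if block_and:
                    and_hits = block_and if and_hits is None else (and_hits | block_and)
            and_set = and_hits or set()
            return SearchResult(self._ranked(and_set), self._ranked(or_hits - and_set))
        raise ValueError(f"unknown search mode: {mode}")

    # -- table -> ontology term assignment ---------------------------------

    def assign_ontology_term(
        self,
        table_text: list[str],
        ontology_terms: dict[str, str],
        background: dict[str, float],
        cutoff: float = 0.01,
    ) -> tuple[str, float] | None:
        """Assign the ontology term whose label words are most over-represented.

        For each candidate term the label's words (and the full label as a
        phrase, when multi-word) are counted in the table's bag of words;
        significance is the binomial upper tail P(X >= k | n, p_background),
        Bonferroni-corrected over the candidate terms. Returns (term_id,
        corrected p) for the winner, or None when nothing clears ``cutoff``.
        """
        words = [_norm(w) for w in table_text if _norm(w)]
        if not words:
            return None
        n = len(words)
        counts: dict[str, int] = {}
        for w in words:
            counts[w] = counts.get(w, 0) + 1
        bigrams: dict[str, int] = {}
        for a, b in zip(words, words[1:]):
            key = f"{a} {b}"
            bigrams[key] = bigrams.get(key, 0) + 1

        results: list[tuple[float, str]] = []
        for term_id, label in ontology_terms.items():
            label_words = [_norm(w) for w in str(label).split()]
            if len(label_words) == 1:
                k = counts.get(label_words[0], 0)
                p_bg = background.get(label_words[0], 0.0)
            else:
                phrase = " ".join(label_words)
                k = bigrams.get(phrase, 0) if len(label_words) == 2 else 0
                p_bg = background.get(phrase, 0.0)
                if p_bg == 0.0:
                    # fall back to the product of word frequencies
                    p_bg = 1.0
                    for w in label_words:
                        p_bg *= background.get(w, 0.0)
            if k == 0 or p_bg <= 0.0:
                continue
            p = float(binom.sf(k - 1, n, min(p_bg, 1.0)))
            results.append((p, term_id))
        if not results:
            return None
        m = len(ontology_terms)
        p_best, term_best = min(results)
        p_corr = min(1.0, p_best * m)
        if p_corr > cutoff:
            return None
        return term_best, p_corr

    # -- file ingestion ----------------------------------------------------

    def load_mapping_file(self, path) -> dict:
        """Load a tab-delimited assertion table.

        Columns: source_id, entity_key, organism, entity_type, name
        (one row per (source, entity, name) assertion).
        """
        import pandas as pd

        df = pd.read_csv(
            path, sep="\t",
            names=["source_id", "entity_key", "organism", "entity_type", "name"],
            header=None, comment="#", dtype=str,
        )
        if list(df.iloc[0]) == ["source_id", "entity_key", "organism", "entity_type", "name"]:
            df = df.iloc[1:]
        grouped: dict[tuple[str, str, str, str], list[str]] = {}
        for row in df.itertuples(index=False):
            key = (row.source_id, row.entity_key, row.organism, row.entity_type)
            grouped.setdefault(key, []).append(row.name)
        recs = [
            SourceRecord(source_id=s, entity_key=e, organism=o, entity_type=t,
                         names=tuple(names))
            for (s, e, o, t), names in grouped.items()
        ]
        return self.register_source(recs)

    def set_properties(self, canonical_id: str, properties: dict[str, str]) -> None:
        if canonical_id not in self.entities:
            raise NotFoundError(f"unknown entity: {canonical_id}")
        self.entities[canonical_id].properties.update(properties)

    def find_by_name(self, name: str, organism: str | None = None) -> list[EntityRecord]:
        return self._ranked(self._match_simple(name, organism))
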