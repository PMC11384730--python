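"""Data model for enzyme-chemistry annotated corpora.

An annotated corpus holds PubMed abstracts in which chemical and protein
mentions are tagged with database identifiers (ChEBI/MeSH for chemicals,
UniProtKB accessions for proteins) and chemical conversions are curated as
relations between mention pairs, optionally with enzyme "Converter" roles
forming ternary tuples.

Character offsets are 0-based, half-open, over the concatenated document
text (passage offsets included), following the BioC convention.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

ENTITY_TYPES = ("Chemical", "Protein", "Domain", "MutantEnzyme", "Coreference")
#: Entity types scored in NER/NEN evaluation. Domain, MutantEnzyme and
#: Coreference mentions are curated only when they participate in
#: conversions, so they are excluded from evaluation and from IOB2 encoding
#: by default.
EVALUATED_ENTITY_TYPES = ("Chemical", "Protein")
RELATION_TYPES = ("Conversion", "Indirect_conversion", "Non_conversion")
#: Identifier namespaces treated as chemical when deciding whether a
#: Coreference mention stands in for a chemical or a protein.
CHEMICAL_NAMESPACES = ("CHEBI:", "MESH:")


class CorpusValidationError(ValueError):
    """Raised when a corpus violates the schema invariants."""


@dataclass(frozen=True, order=True)
class Span:
    """Half-open character interval [start, end) over the document text."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class EntityMention:
    """A typed, identifier-bearing text span.

    ``identifiers`` is an ordered list of namespaced IDs (``CHEBI:n``,
    ``MESH:Dnnnnnn``, UniProtKB accessions). A mention without identifiers
    is scored as carrying the single empty-string ID.
    """

    mention_id: str
    span: Span
    surface: str
    entity_type: str
    identifiers: list[str] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    def id_key(self) -> tuple[str, ...]:
        """Canonical identifier set used for matching and deduplication."""
        ids = [i for i in self.identifiers if i]
        return tuple(sorted(set(ids))) if ids else ("",)

    def is_chemical_like(self) -> bool:
        if self.entity_type == "Chemical":
            return True
        if self.entity_type == "Coreference":
            return any(i.startswith(CHEMICAL_NAMESPACES) for i in self.identifiers)
        return False

    def is_protein_like(self) -> bool:
        if self.entity_type in ("Protein", "Domain", "MutantEnzyme"):
            return True
        if self.entity_type == "Coreference":
            return bool(self.identifiers) and not any(
                i.startswith(CHEMICAL_NAMESPACES) for i in self.identifiers
            )
        return False


@dataclass
class RelationRecord:
    """A curated chemical conversion between two mentions.

    ``relation_type`` is one of Conversion / Indirect_conversion /
    Non_conversion; the synthetic "None" label exists only during instance
    enumeration and is never serialized. ``converters`` lists the protein
    mentions playing the Converter role (empty for binary-only relations).
    """

    relation_id: str
    relation_type: str
    chem_a: str
    chem_b: str
    converters: list[str] = field(default_factory=list)
    sentence_index: int | None = None
    infons: dict[str, str] = field(default_factory=dict)


@dataclass
class Passage:
    offset: int
    text: str
    infons: dict[str, str] = field(default_factory=dict)


@dataclass
class AnnotatedDocument:
    """One abstract: passages plus mention and relation annotations."""

    pmid: str
    passages: list[Passage] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)
    relations: list[RelationRecord] = field(default_factory=list)
    infons: dict[str, str] = field(default_factory=dict)

    def text(self) -> str:
        """Concatenated document text with passage offsets honoured.

        Gaps between passages (BioC offsets may skip separator characters)
        are padded with spaces so that annotation offsets index directly.
        """
        buf: list[str] = []
        pos = 0
        for p in self.passages:
            if p.offset < pos:
                raise CorpusValidationError(
                    f"pmid {self.pmid}: passage offsets not strictly increasing"
                )
            buf.append(" " * (p.offset - pos))
            buf.append(p.text)
            pos = p.offset + len(p.text)
        return "".join(buf)

    def mention_by_id(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise KeyError(mention_id)


@dataclass
class Corpus:
    documents: list[AnnotatedDocument] = field(default_factory=list)
    provenance: str = ""

    def __iter__(self) -> Iterator[AnnotatedDocument]:
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def pmids(self) -> list[str]:
        return [d.pmid for d in self.documents]


def validate_corpus(corpus: Corpus, check_surfaces: bool = True) -> None:
    """Check schema invariants, raising :class:`CorpusValidationError`.

    Checks: unique pmids; known entity and relation types; relation
    participants resolve to existing mentions of the right kind; chem_a and
    chem_b are distinct mentions; span text equals the recorded surface.
    """
    seen_pmids: set[str] = set()
    for doc in corpus:
        if doc.pmid in seen_pmids:
            raise CorpusValidationError(f"duplicate pmid {doc.pmid}")
        seen_pmids.add(doc.pmid)
        text = doc.text()
        mention_ids: dict[str, EntityMention] = {}
        for m in doc.mentions:
            if m.entity_type not in ENTITY_TYPES:
                raise CorpusValidationError(
                    f"pmid {doc.pmid}: unknown entity type {m.entity_type!r}"
                )
            if m.mention_id in mention_ids:
                raise CorpusValidationError(
                    f"pmid {doc.pmid}: duplicate mention id {m.mention_id}"
                )
            mention_ids[m.mention_id] = m
            if m.span.end > len(text):
                raise CorpusValidationError(
                    f"pmid {doc.pmid}: mention {m.mention_id} span exceeds text"
                )
            if check_surfaces and text[m.span.start : m.span.end] != m.surface:
                raise CorpusValidationError(
                    f"pmid {doc.pmid}: mention {m.mention_id} surface mismatch: "
                    f"{text[m.span.start:m.span.end]!r} != {m.surface!r}"
                )
        for r in doc.relations:
            if r.relation_type not in RELATION_TYPES:
                raise CorpusValidationError(
                    f"pmid {doc.pmid}: relation {r.relation_id} has invalid type "
                    f"{r.relation_type!r}"
                )
            for ref in (r.chem_a, r.chem_b, *r.converters):
                if ref not in mention_ids:
                    raise CorpusValidationError(
                        f"pmid {doc.pmid}: relation {r.relation_id} references "
                        f"missing annotation {ref!r}"
                    )
            if r.chem_a == r.chem_b:
                raise CorpusValidationError(
                    f"pmid {doc.pmid}: relation {r.relation_id} links a mention "
                    "to itself"
                )
            for ref in (r.chem_a, r.chem_b):
                if not mention_ids[ref].is_chemical_like():
                    raise CorpusValidationError(
                        f"pmid {doc.pmid}: relation {r.relation_id} chemical ref "
                        f"{ref} is not a chemical mention"
                    )
            for ref in r.converters:
                if not mention_ids[ref].is_protein_like():
                    raise CorpusValidationError(
                        f"pmid {doc.pmid}: relation {r.relation_id} converter "
                        f"{ref} is not a protein-like mention"
                    )


# ---------------------------------------------------------------------------
# Corpus statistics


@dataclass
class CorpusStats:
    """Summary-table counts: mentions / pairs / tuples and unique IDs.

    ``entity_mentions[t]`` counts every mention occurrence of type ``t``;
    ``entity_unique_ids[t]`` counts distinct identifiers (a composite
    mention contributes each of its IDs once). Binary pairs count relation
    records per type, deduplicated as unordered ID-set pairs; ternary
    tuples count (relation, converter) occurrences, deduplicated as
    (unordered pair, converter ID-set). Each block carries an "All" total
    equal to the sum of its parts (unique "All" is the union).
    """

    n_documents: int
    entity_mentions: dict[str, int]
    entity_unique_ids: dict[str, int]
    binary_pairs: dict[str, int]
    binary_unique_pairs: dict[str, int]
    ternary_tuples: dict[str, int]
    ternary_unique_tuples: dict[str, int]

    def as_dict(self) -> dict:
        return {
            "documents": self.n_documents,
            "entity_mentions": self.entity_mentions,
            "entity_unique_ids": self.entity_unique_ids,
            "binary_pairs": self.binary_pairs,
            "binary_unique_pairs": self.binary_unique_pairs,
            "ternary_tuples": self.ternary_tuples,
            "ternary_unique_tuples": self.ternary_unique_tuples,
        }


def _pair_key(a: EntityMention, b: EntityMention):
    # Unordered pair of canonical ID sets; collapses when both members share
    # an ID set (e.g. a synonym mention), which is the wanted dedup behaviour.
    return frozenset((a.id_key(), b.id_key()))


def corpus_statistics(corpus: Corpus) -> CorpusStats:
    """Compute summary-table statistics for a corpus.

    Raw counts tally every occurrence; unique counts deduplicate by
    identifier across the whole corpus. An empty corpus yields all zeros.
    """
    mention_counts = {t: 0 for t in ENTITY_TYPES}
    unique_ids: dict[str, set[str]] = {t: set() for t in ENTITY_TYPES}
    pair_counts = {t: 0 for t in RELATION_TYPES}
    unique_pairs: dict[str, set] = {t: set() for t in RELATION_TYPES}
    tuple_counts = {t: 0 for t in RELATION_TYPES}
    unique_tuples: dict[str, set] = {t: set() for t in RELATION_TYPES}

    for doc in corpus:
        index = {m.mention_id: m for m in doc.mentions}
        for m in doc.mentions:
            mention_counts[m.entity_type] += 1
            unique_ids[m.entity_type].update(i for i in m.identifiers if i)
        for r in doc.relations:
            a, b = index[r.chem_a], index[r.chem_b]
            key = _pair_key(a, b)
            pair_counts[r.relation_type] += 1
            unique_pairs[r.relation_type].add(key)
            for conv in r.converters:
                tuple_counts[r.relation_type] += 1
                unique_tuples[r.relation_type].add((key, index[conv].id_key()))

    def with_all(counts: dict[str, int]) -> dict[str, int]:
        return {"All": sum(counts.values()), **counts}

    def union_all(sets: dict[str, set]) -> dict[str, int]:
        return {
            "All": len(set().union(*sets.values())) if sets else 0,
            **{k: len(v) for k, v in sets.items()},
        }

    return CorpusStats(
        n_documents=len(corpus),
        entity_mentions=with_all(mention_counts),
        entity_unique_ids=union_all(unique_ids),
        binary_pairs=with_all(pair_counts),
        binary_unique_pairs=union_all(unique_pairs),
        ternary_tuples=with_all(tuple_counts),
        ternary_unique_tuples=union_all(unique_tuples),
    )


# ---------------------------------------------------------------------------
# Inter-annotator agreement


def _entity_keys(corpus: Corpus) -> set:
    keys = set()
    for doc in corpus:
        for m in doc.mentions:
            keys.add((doc.pmid, m.entity_type, m.span, m.id_key()))
    return keys


def _pair_keys(corpus: Corpus) -> set:
    keys = set()
    for doc in corpus:
        index = {m.mention_id: m for m in doc.mentions}
        for r in doc.relations:
            a, b = index[r.chem_a], index[r.chem_b]
            pk = frozenset(((a.span, a.id_key()), (b.span, b.id_key())))
            keys.add((doc.pmid, pk, r.relation_type))
    return keys


def compute_iaa(corpus_a: Corpus, corpus_b: Corpus, level: str = "entity") -> float:
    """Inter-annotator agreement between two curation copies, as F1 (%).

    At ``entity`` level a match requires identical span, entity type and
    identifier set; at ``binary_pair`` level identical chemical spans and
    identifier sets plus the relation type. Agreement is the F1 between the
    two annotation sets, which is symmetric in the corpora.
    """
    if set(corpus_a.pmids()) != set(corpus_b.pmids()):
        diff = sorted(set(corpus_a.pmids()) ^ set(corpus_b.pmids()))
        raise ValueError(f"corpora cover different pmids: {diff}")
    if level == "entity":
        ka, kb = _entity_keys(corpus_a), _entity_keys(corpus_b)
    elif level in ("binary_pair", "pair"):
        ka, kb = _pair_keys(corpus_a), _pair_keys(corpus_b)
    else:
        raise ValueError(f"unknown IAA level {level!r}")
    tp = len(ka & kb)
    fp = len(kb - ka)
    fn = len(ka - kb)
    if tp == 0:
        return 0.0
    p = tp / (tp + fp)
    r = tp / (tp + fn)
    return 200.0 * p * r / (p + r)
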