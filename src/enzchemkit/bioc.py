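"""BioC XML reader and writer for the enzyme-chemistry corpus dialect.

The dialect is PubTator-style BioC: annotations carry ``type`` and
``identifier`` infons (identifiers comma-separated, empty string when a
mention has no database ID), and relations reference annotation ids through
``node`` elements whose roles name the two chemicals and any enzyme
Converters. Unknown infons are preserved round-trip as opaque metadata.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from lxml import etree

from .corpus import (
    AnnotatedDocument,
    Corpus,
    CorpusValidationError,
    EntityMention,
    Passage,
    RelationRecord,
    Span,
)


class BiocParseError(ValueError):
    """Raised when a file is not well-formed BioC XML."""


@dataclass
class BiocDialect:
    """Serialization keys that the released corpus does not pin down."""

    chemical_roles: tuple[str, str] = ("Chemical1", "Chemical2")
    converter_role: str = "Converter"
    identifier_infon: str = "identifier"
    type_infon: str = "type"
    sentence_infon: str = "sentence_index"
    identifier_sep: str = ","


DEFAULT_DIALECT = BiocDialect()

_RESERVED_DOC_INFONS = frozenset()


def _infons(parent: etree._Element) -> dict[str, str]:
    return {e.get("key"): (e.text or "") for e in parent.findall("infon")}


def _write_infons(parent: etree._Element, infons: dict[str, str]) -> None:
    for key, value in infons.items():
        if not isinstance(value, str):
            raise CorpusValidationError(
                f"infon {key!r} has unserializable value {value!r}"
            )
        e = etree.SubElement(parent, "infon", key=key)
        e.text = value


def read_bioc(path: str | os.PathLike, dialect: BiocDialect = DEFAULT_DIALECT) -> Corpus:
    """Read a BioC XML collection into a :class:`Corpus`.

    A BioC annotation with multiple locations is split into one mention per
    location with shared identifiers. A relation node referencing a missing
    annotation id raises :class:`CorpusValidationError` naming the document
    and relation.
    """
    try:
        tree = etree.parse(os.fspath(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise BiocParseError(f"cannot parse BioC file {path}: {exc}") from exc
    root = tree.getroot()
    if root.tag != "collection":
        raise BiocParseError(f"{path}: root element is {root.tag!r}, not collection")

    source = root.findtext("source") or ""
    corpus = Corpus(provenance=source)
    for doc_el in root.findall("document"):
        pmid = doc_el.findtext("id") or ""
        doc = AnnotatedDocument(pmid=pmid, infons=_infons(doc_el))
        ann_ids: set[str] = set()
        rel_els: list[etree._Element] = []
        for pas_el in doc_el.findall("passage"):
            offset = int(pas_el.findtext("offset") or 0)
            text = pas_el.findtext("text") or ""
            doc.passages.append(Passage(offset=offset, text=text, infons=_infons(pas_el)))
            for ann_el in pas_el.findall("annotation"):
                for m in _read_annotation(ann_el, dialect):
                    doc.mentions.append(m)
                    ann_ids.add(m.mention_id)
            rel_els.extend(pas_el.findall("relation"))
        for rel_el in rel_els + doc_el.findall("relation"):
            doc.relations.append(_read_relation(rel_el, pmid, ann_ids, dialect))
        corpus.documents.append(doc)
    return corpus


def _read_annotation(ann_el: etree._Element, dialect: BiocDialect) -> list[EntityMention]:
    infons = _infons(ann_el)
    etype = infons.pop(dialect.type_infon, "Chemical")
    ident = infons.pop(dialect.identifier_infon, "")
    identifiers = [i for i in ident.split(dialect.identifier_sep) if i] if ident else []
    surface = ann_el.findtext("text") or ""
    locations = ann_el.findall("location")
    base_id = ann_el.get("id", "")
    mentions = []
    for i, loc in enumerate(locations):
        start = int(loc.get("offset"))
        length = int(loc.get("length"))
        mid = base_id if len(locations) == 1 else f"{base_id}.{i}"
        mentions.append(
            EntityMention(
                mention_id=mid,
                span=Span(start, start + length),
                surface=surface,
                entity_type=etype,
                identifiers=list(identifiers),
                infons=infons.copy(),
            )
        )
    return mentions


def _read_relation(
    rel_el: etree._Element, pmid: str, ann_ids: set[str], dialect: BiocDialect
) -> RelationRecord:
    infons = _infons(rel_el)
    rtype = infons.pop(dialect.type_infon, "")
    sent = infons.pop(dialect.sentence_infon, None)
    rel_id = rel_el.get("id", "")
    chems: dict[str, str] = {}
    converters: list[str] = []
    for node in rel_el.findall("node"):
        refid, role = node.get("refid"), node.get("role", "")
        if refid not in ann_ids:
            raise CorpusValidationError(
                f"pmid {pmid}: relation {rel_id} references missing annotation "
                f"{refid!r}"
            )
        if role in dialect.chemical_roles:
            chems[role] = refid
        elif role == dialect.converter_role:
            converters.append(refid)
        else:
            raise CorpusValidationError(
                f"pmid {pmid}: relation {rel_id} has unknown role {role!r}"
            )
    if set(chems) != set(dialect.chemical_roles):
        raise CorpusValidationError(
            f"pmid {pmid}: relation {rel_id} lacks two chemical participants"
        )
    return RelationRecord(
        relation_id=rel_id,
        relation_type=rtype,
        chem_a=chems[dialect.chemical_roles[0]],
        chem_b=chems[dialect.chemical_roles[1]],
        converters=converters,
        sentence_index=int(sent) if sent is not None else None,
        infons=infons,
    )


def write_bioc(
    corpus: Corpus, path: str | os.PathLike, dialect: BiocDialect = DEFAULT_DIALECT
) -> None:
    """Write a :class:`Corpus` as BioC XML; inverse of :func:`read_bioc`.

    Each mention is serialized inside the passage containing its span, with
    identifiers joined into a single ``identifier`` infon (empty string
    when the mention has none). Relations are serialized at document level.
    """
    root = etree.Element("collection")
    etree.SubElement(root, "source").text = corpus.provenance
    etree.SubElement(root, "date").text = ""
    etree.SubElement(root, "key").text = ""
    for doc in corpus:
        doc_el = etree.SubElement(root, "document")
        etree.SubElement(doc_el, "id").text = doc.pmid
        _write_infons(doc_el, doc.infons)
        for p_i, passage in enumerate(doc.passages):
            pas_el = etree.SubElement(doc_el, "passage")
            _write_infons(pas_el, passage.infons)
            etree.SubElement(pas_el, "offset").text = str(passage.offset)
            etree.SubElement(pas_el, "text").text = passage.text
            p_end = passage.offset + len(passage.text)
            for m in doc.mentions:
                if passage.offset <= m.span.start < p_end or (
                    p_i == 0 and m.span.start < passage.offset
                ):
                    _write_annotation(pas_el, m, dialect)
        for r in doc.relations:
            _write_relation(doc_el, r, dialect)
    tree = etree.ElementTree(root)
    tree.write(
        os.fspath(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def _write_annotation(
    pas_el: etree._Element, m: EntityMention, dialect: BiocDialect
) -> None:
    ann_el = etree.SubElement(pas_el, "annotation", id=m.mention_id)
    infons = {
        dialect.type_infon: m.entity_type,
        dialect.identifier_infon: dialect.identifier_sep.join(m.identifiers),
        **m.infons,
    }
    _write_infons(ann_el, infons)
    etree.SubElement(
        ann_el,
        "location",
        offset=str(m.span.start),
        length=str(len(m.span)),
    )
    etree.SubElement(ann_el, "text").text = m.surface


def _write_relation(
    doc_el: etree._Element, r: RelationRecord, dialect: BiocDialect
) -> None:
    rel_el = etree.SubElement(doc_el, "relation", id=r.relation_id)
    infons = {dialect.type_infon: r.relation_type, **r.infons}
    if r.sentence_index is not None:
        infons[dialect.sentence_infon] = str(r.sentence_index)
    _write_infons(rel_el, infons)
    for role, ref in zip(dialect.chemical_roles, (r.chem_a, r.chem_b)):
        etree.SubElement(rel_el, "node", refid=ref, role=role)
    for conv in r.converters:
        etree.SubElement(rel_el, "node", refid=conv, role=dialect.converter_role)
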