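"""Classification-instance enumeration for chemical conversions.

Relation extraction over a curated document is framed at sentence level:
every unordered pair of chemical mentions co-occurring in a sentence is a
binary instance, and every (protein mention, chemical pair) cross product
a ternary instance. Instances matching a curated relation carry its label
(Conversion / Indirect_conversion / Non_conversion); all others are
synthesized as "None" — in the ternary case also when the pair is curated
but the protein is not among that relation's Converters. Repeated protein
mentions give distinct instances.

``render`` produces the tagged input representation used by sentence-level
relation classifiers: a task tag prefix plus boundary markers around the
chemical pair and (for ternary instances) the protein.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .corpus import AnnotatedDocument, EntityMention, RelationRecord, Span
from . import ner

log = logging.getLogger(__name__)

NONE_LABEL = "None"


@dataclass(frozen=True)
class TagDialect:
    """Marker texts for the rendered input representation."""

    task_tag: str = "[Reaction]"
    chem1_tags: tuple[str, str] = ("<C1>", "</C1>")
    chem2_tags: tuple[str, str] = ("<C2>", "</C2>")
    protein_tags: tuple[str, str] = ("<P>", "</P>")


DEFAULT_DIALECT = TagDialect()


@dataclass
class BinaryInstance:
    """A chemical mention pair within one sentence, with its gold label."""

    pmid: str
    sentence_index: int
    sentence_span: Span
    chem_a: EntityMention
    chem_b: EntityMention
    gold_label: str = NONE_LABEL

    def __post_init__(self) -> None:
        # canonical ordering by span start
        if self.chem_a.span > self.chem_b.span:
            self.chem_a, self.chem_b = self.chem_b, self.chem_a


@dataclass
class TernaryInstance(BinaryInstance):
    protein: EntityMention | None = None


def _sentence_of(span: Span, sentences: list[Span]) -> int | None:
    for i, s in enumerate(sentences):
        if s.contains(span):
            return i
    return None


def _relation_index(doc: AnnotatedDocument) -> dict[frozenset, RelationRecord]:
    index: dict[frozenset, RelationRecord] = {}
    for r in doc.relations:
        index[frozenset((r.chem_a, r.chem_b))] = r
    return index


def _grouped_mentions(doc: AnnotatedDocument, sentences: list[Span]):
    """Chemical-like and protein-like mentions per sentence index."""
    chems: dict[int, list[EntityMention]] = {}
    prots: dict[int, list[EntityMention]] = {}
    for m in doc.mentions:
        si = _sentence_of(m.span, sentences)
        if si is None:
            continue
        if m.is_chemical_like():
            chems.setdefault(si, []).append(m)
        elif m.is_protein_like():
            prots.setdefault(si, []).append(m)
    return chems, prots


def enumerate_binary(
    doc: AnnotatedDocument, sentences: list[Span] | None = None
) -> list[BinaryInstance]:
    """All in-sentence chemical mention pairs with gold labels.

    Curated relations whose mentions straddle sentence boundaries are
    logged and skipped for instance generation (they stay in the corpus).
    """
    if sentences is None:
        sentences = ner.sentence_spans(doc.text())
    chems, _ = _grouped_mentions(doc, sentences)
    rel_index = _relation_index(doc)
    seen_pairs: set[frozenset] = set()
    out: list[BinaryInstance] = []
    for si in sorted(chems):
        group = sorted(chems[si], key=lambda m: m.span)
        for i in range(len(group)):
            for j in range(i + 1, len(group)):
                a, b = group[i], group[j]
                key = frozenset((a.mention_id, b.mention_id))
                rel = rel_index.get(key)
                if rel is not None:
                    seen_pairs.add(key)
                out.append(
                    BinaryInstance(
                        pmid=doc.pmid,
                        sentence_index=si,
                        sentence_span=sentences[si],
                        chem_a=a,
                        chem_b=b,
                        gold_label=rel.relation_type if rel else NONE_LABEL,
                    )
                )
    for key, rel in rel_index.items():
        if key not in seen_pairs:
            log.info(
                "pmid %s: relation %s spans sentences; skipped for instances",
                doc.pmid, rel.relation_id,
            )
    return out


def enumerate_ternary(
    doc: AnnotatedDocument, sentences: list[Span] | None = None
) -> list[TernaryInstance]:
    """Cross product of in-sentence proteins with in-sentence chemical pairs.

    The label is the pair's curated relation type when the protein is among
    that relation's Converters, else "None".
    """
    if sentences is None:
        sentences = ner.sentence_spans(doc.text())
    chems, prots = _grouped_mentions(doc, sentences)
    rel_index = _relation_index(doc)
    out: list[TernaryInstance] = []
    for si in sorted(chems):
        if si not in prots:
            continue
        chem_group = sorted(chems[si], key=lambda m: m.span)
        prot_group = sorted(prots[si], key=lambda m: m.span)
        for p in prot_group:
            for i in range(len(chem_group)):
                for j in range(i + 1, len(chem_group)):
                    a, b = chem_group[i], chem_group[j]
                    rel = rel_index.get(frozenset((a.mention_id, b.mention_id)))
                    if rel is not None and p.mention_id in rel.converters:
                        label = rel.relation_type
                    else:
                        label = NONE_LABEL
                    out.append(
                        TernaryInstance(
                            pmid=doc.pmid,
                            sentence_index=si,
                            sentence_span=sentences[si],
                            chem_a=a,
                            chem_b=b,
                            protein=p,
                            gold_label=label,
                        )
                    )
    return out


def render(
    instance: BinaryInstance,
    text: str,
    dialect: TagDialect = DEFAULT_DIALECT,
) -> str:
    """Tagged sentence text for one instance.

    The task tag is prefixed and boundary markers wrap the chemical pair
    (and the protein for ternary instances); original characters are
    preserved. Insertions are applied right-to-left so offsets stay valid.
    Overlapping target mentions cannot be nested and raise ``ValueError``.
    """
    sent = instance.sentence_span
    targets: list[tuple[Span, tuple[str, str]]] = [
        (instance.chem_a.span, dialect.chem1_tags),
        (instance.chem_b.span, dialect.chem2_tags),
    ]
    if isinstance(instance, TernaryInstance) and instance.protein is not None:
        targets.append((instance.protein.span, dialect.protein_tags))
    for i in range(len(targets)):
        for j in range(i + 1, len(targets)):
            if targets[i][0].overlaps(targets[j][0]):
                raise ValueError(
                    f"overlapping target mentions {targets[i][0]} and "
                    f"{targets[j][0]} cannot be marked"
                )
    chunk = text[sent.start : sent.end]
    for span, (open_tag, close_tag) in sorted(targets, reverse=True):
        s, e = span.start - sent.start, span.end - sent.start
        chunk = chunk[:s] + open_tag + chunk[s:e] + close_tag + chunk[e:]
    prefix = dialect.task_tag + " " if dialect.task_tag else ""
    return prefix + chunk


# ---------------------------------------------------------------------------
# Deterministic trigger-word baseline

_CONVERSION_TRIGGERS = (
    "converts", "converted", "conversion of", "catalyzes the conversion",
    "hydrolyzes", "hydrolysis of", "formed", "forming", "forms", "yields",
    "to yield", "producing", "produces", "synthesizes",
)
_INDIRECT_TRIGGERS = (
    "series of", "intermediates", "indirectly", "via several steps",
    "through a series", "catabolized", "pathway",
)
_NEGATION_TRIGGERS = (
    "no detectable", "did not convert", "no conversion", "not converted",
    "failed to convert", "with no detectable formation",
)


def baseline_classify(rendered: str) -> str:
    """Naive trigger-word relation classifier over a rendered instance.

    A deterministic baseline for exercising evaluation and end-to-end
    plumbing; it is not a substitute for a trained relation classifier and
    its failure modes (e.g. "respectively" constructions) are intentional
    test material. Negation triggers beat indirect triggers beat plain
    conversion triggers.
    """
    lowered = rendered.lower()
    if any(t in lowered for t in _NEGATION_TRIGGERS):
        return "Non_conversion"
    if any(t in lowered for t in _INDIRECT_TRIGGERS):
        return "Indirect_conversion"
    if any(t in lowered for t in _CONVERSION_TRIGGERS):
        return "Conversion"
    return NONE_LABEL


def write_instances_tsv(instances, text_by_pmid: dict[str, str], fh,
                        dialect: TagDialect = DEFAULT_DIALECT) -> None:
    """Write instances as TSV: pmid, sentence, offsets, IDs, label, text."""
    header = [
        "pmid", "sentence_index", "chem_a_span", "chem_b_span",
        "chem_a_ids", "chem_b_ids", "protein_span", "protein_ids",
        "label", "rendered",
    ]
    fh.write("\t".join(header) + "\n")
    for inst in instances:
        prot = getattr(inst, "protein", None)
        row = [
            inst.pmid,
            str(inst.sentence_index),
            f"{inst.chem_a.span.start}-{inst.chem_a.span.end}",
            f"{inst.chem_b.span.start}-{inst.chem_b.span.end}",
            ",".join(inst.chem_a.id_key()),
            ",".join(inst.chem_b.id_key()),
            f"{prot.span.start}-{prot.span.end}" if prot else "",
            ",".join(prot.id_key()) if prot else "",
            inst.gold_label,
            render(inst, text_by_pmid[inst.pmid], dialect),
        ]
        fh.write("\t".join(row) + "\n")
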