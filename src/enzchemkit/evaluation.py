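"""Scoring contracts for NER, NEN, relation extraction, and end-to-end runs.

All scores are micro-averaged precision/recall/F1 percentages computed
from exact-match keys:

* NER: (pmid, entity type, span) — only Chemical and Protein mentions are
  scored, since the other types are not systematically curated;
* NEN: NER key plus identifier-set equality (a mention with no identifier
  carries the empty-string ID, which matches only itself);
* relation instances: pmid, both chemical spans and ID sets, and the
  relation type — "binary" classification treats Conversion and
  Indirect_conversion as equivalent while "multiclass" keeps them
  distinct; None-labelled instances are negatives and never true
  positives; ternary keys add the protein span and ID set;
* end-to-end: relation matching under binary classification where,
  optionally ("relaxed"), a predicted ChEBI ID may also match a direct
  parent or child of the gold ID in the ChEBI is_a hierarchy. MeSH and
  other namespaces always require exact equality.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx

from .corpus import Corpus, EVALUATED_ENTITY_TYPES
from .instances import BinaryInstance, TernaryInstance, NONE_LABEL


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 (percent) with the underlying counts."""

    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0

    def __add__(self, other: "PRF") -> "PRF":
        return PRF(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def _check_pmids(gold: Corpus, pred: Corpus) -> None:
    if set(gold.pmids()) != set(pred.pmids()):
        diff = sorted(set(gold.pmids()) ^ set(pred.pmids()))
        raise ValueError(f"gold and predicted corpora cover different pmids: {diff}")


def _mention_keys(corpus: Corpus, with_ids: bool) -> dict[str, set]:
    keys: dict[str, set] = {t: set() for t in EVALUATED_ENTITY_TYPES}
    for doc in corpus:
        for m in doc.mentions:
            if m.entity_type not in keys:
                continue
            key = (doc.pmid, m.span.start, m.span.end)
            if with_ids:
                key = key + (m.id_key(),)
            keys[m.entity_type].add(key)
    return keys


def _prf_from_sets(gold: set, pred: set) -> PRF:
    tp = len(gold & pred)
    return PRF(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


def _score_mentions(gold: Corpus, pred: Corpus, with_ids: bool) -> dict[str, PRF]:
    _check_pmids(gold, pred)
    gk = _mention_keys(gold, with_ids)
    pk = _mention_keys(pred, with_ids)
    scores = {t: _prf_from_sets(gk[t], pk[t]) for t in EVALUATED_ENTITY_TYPES}
    scores["Overall"] = sum(scores.values(), PRF(0, 0, 0))
    return scores


def evaluate_ner(gold: Corpus, pred: Corpus) -> dict[str, PRF]:
    """Span-level NER scores: a TP requires matching type and offsets."""
    return _score_mentions(gold, pred, with_ids=False)


def evaluate_nen(gold: Corpus, pred: Corpus) -> dict[str, PRF]:
    """NER+NEN scores: a TP additionally requires identifier-set equality."""
    return _score_mentions(gold, pred, with_ids=True)


def macro_f1(scores: dict[str, PRF]) -> float:
    """Macro-averaged F1 over the per-type entries (excluding Overall)."""
    per_type = [v.f1 for k, v in scores.items() if k != "Overall"]
    return sum(per_type) / len(per_type) if per_type else 0.0


# ---------------------------------------------------------------------------
# Relation instances

_BINARY_COLLAPSE = {"Indirect_conversion": "Conversion"}


def _collapse(label: str, mode: str) -> str:
    if mode == "binary":
        return _BINARY_COLLAPSE.get(label, label)
    return label


def instance_key(inst: BinaryInstance, arity: int):
    """Canonical match key: pmid, ordered chemical spans and ID sets,
    plus the protein span and ID set for ternary instances."""
    a, b = sorted((inst.chem_a, inst.chem_b), key=lambda m: m.span)
    key = (
        inst.pmid,
        a.span.start, a.span.end, a.id_key(),
        b.span.start, b.span.end, b.id_key(),
    )
    if arity == 3:
        p = inst.protein
        if p is None:
            raise ValueError("ternary evaluation requires protein mentions")
        key = key + (p.span.start, p.span.end, p.id_key())
    return key


def evaluate_relations(
    gold_instances: Sequence[BinaryInstance],
    pred_instances: Sequence[BinaryInstance],
    arity: int = 2,
    mode: str = "binary",
) -> PRF:
    """Score predicted relation instances against gold.

    ``mode='binary'`` collapses Conversion and Indirect_conversion into one
    positive class (Non_conversion stays distinct); ``'multiclass'`` keeps
    all three apart. Instances labelled None are negatives on either side.
    Duplicate instance keys raise ``ValueError``.
    """
    if mode not in ("binary", "multiclass"):
        raise ValueError(f"unknown mode {mode!r}")

    def labelled(instances: Sequence[BinaryInstance]) -> dict:
        out: dict = {}
        for inst in instances:
            key = instance_key(inst, arity)
            if key in out:
                raise ValueError(f"duplicate instance key {key}")
            out[key] = _collapse(inst.gold_label, mode)
        return out

    gold = {k: v for k, v in labelled(gold_instances).items() if v != NONE_LABEL}
    pred = {k: v for k, v in labelled(pred_instances).items() if v != NONE_LABEL}
    tp = sum(1 for k, v in pred.items() if gold.get(k) == v)
    return PRF(tp=tp, fp=len(pred) - tp, fn=len(gold) - tp)


# ---------------------------------------------------------------------------
# ChEBI ontology and relaxed end-to-end matching


class OntologyGraph:
    """Directed is_a edges over ChEBI IDs (child -> parent), acyclic."""

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]]) -> "OntologyGraph":
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("is_a hierarchy contains a cycle")
        return cls(g)

    @classmethod
    def from_obo(cls, path: str | os.PathLike) -> "OntologyGraph":
        """Parse an OBO ontology, keeping only is_a edges."""
        import obonet

        multi = obonet.read_obo(os.fspath(path))
        g = nx.DiGraph()
        g.add_nodes_from(multi.nodes)
        for child, parent, key in multi.edges(keys=True):
            if key == "is_a":
                g.add_edge(child, parent)
        return cls(g)

    def adjacent(self, a: str, b: str) -> bool:
        """True when a and b are one is_a edge apart, in either direction."""
        return self.graph.has_edge(a, b) or self.graph.has_edge(b, a)


def _ids_match_relaxed(
    gold_ids: tuple[str, ...], pred_ids: tuple[str, ...], ontology: OntologyGraph
) -> bool:
    """One-to-one pairing of the two ID sets, each pair equal or (for
    ChEBI IDs) one is_a edge apart."""
    if gold_ids == pred_ids:
        return True
    if len(gold_ids) != len(pred_ids):
        return False

    def compatible(g: str, p: str) -> bool:
        if g == p:
            return True
        if g.startswith("CHEBI:") and p.startswith("CHEBI:"):
            return ontology.adjacent(g, p)
        return False

    bip = nx.Graph()
    left = [("g", i) for i in range(len(gold_ids))]
    right = [("p", j) for j in range(len(pred_ids))]
    bip.add_nodes_from(left, bipartite=0)
    bip.add_nodes_from(right, bipartite=1)
    for i, g in enumerate(gold_ids):
        for j, p in enumerate(pred_ids):
            if compatible(g, p):
                bip.add_edge(("g", i), ("p", j))
    matching = nx.bipartite.maximum_matching(bip, top_nodes=left)
    return sum(1 for n in matching if n[0] == "g") == len(gold_ids)


def _pair_items(corpus: Corpus) -> list[tuple]:
    items = []
    for doc in corpus:
        index = {m.mention_id: m for m in doc.mentions}
        for r in doc.relations:
            a, b = sorted(
                (index[r.chem_a], index[r.chem_b]), key=lambda m: m.span
            )
            items.append(
                (
                    doc.pmid,
                    (a.span.start, a.span.end), a.id_key(),
                    (b.span.start, b.span.end), b.id_key(),
                    _collapse(r.relation_type, "binary"),
                )
            )
    return items


def evaluate_end_to_end(
    gold: Corpus,
    pred: Corpus,
    ontology: OntologyGraph | None = None,
    matching: str = "exact",
) -> PRF:
    """Score a predicted corpus (any NER+NEN+RE chain) against gold.

    Relation pairs are matched under binary classification. With
    ``matching='relaxed'`` a chemical's ChEBI ID set may match the gold set
    through one-to-one pairings that are equal or one is_a edge apart in
    the supplied ontology; ``'exact'`` requires ID-set equality.
    """
    if matching not in ("exact", "relaxed"):
        raise ValueError(f"unknown matching {matching!r}")
    if matching == "relaxed" and ontology is None:
        raise ValueError("relaxed matching requires an ontology")
    _check_pmids(gold, pred)
    gold_items = _pair_items(gold)
    pred_items = _pair_items(pred)
    if matching == "exact":
        return _prf_from_sets(set(gold_items), set(pred_items))

    def compatible(g: tuple, p: tuple) -> bool:
        if g[0] != p[0] or g[5] != p[5]:  # pmid, label
            return False
        if g[1] != p[1] or g[3] != p[3]:  # spans
            return False
        return _ids_match_relaxed(g[2], p[2], ontology) and _ids_match_relaxed(
            g[4], p[4], ontology
        )

    bip = nx.Graph()
    left = [("g", i) for i in range(len(gold_items))]
    bip.add_nodes_from(left, bipartite=0)
    bip.add_nodes_from((("p", j) for j in range(len(pred_items))), bipartite=1)
    for i, g in enumerate(gold_items):
        for j, p in enumerate(pred_items):
            if compatible(g, p):
                bip.add_edge(("g", i), ("p", j))
    matching_map = nx.bipartite.maximum_matching(bip, top_nodes=left) if bip.edges else {}
    tp = sum(1 for n in matching_map if n[0] == "g")
    return PRF(tp=tp, fp=len(pred_items) - tp, fn=len(gold_items) - tp)
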