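"""Scoring contracts: PRF arithmetic, RE modes, relaxed ontology matching."""

import copy
import random

import pytest

from enzchemkit.corpus import Corpus
from enzchemkit.evaluation import (
    OntologyGraph,
    PRF,
    evaluate_end_to_end,
    evaluate_nen,
    evaluate_ner,
    evaluate_relations,
    instance_key,
    macro_f1,
)
from enzchemkit.instances import NONE_LABEL, enumerate_binary, enumerate_ternary
from enzchemkit.synthetic import GeneratorConfig, corrupt, generate_corpus

from conftest import make_doc


def test_prf_closed_form():
    prf = PRF(tp=40, fp=5, fn=10)
    assert prf.precision == pytest.approx(88.888888, abs=1e-4)
    assert prf.recall == pytest.approx(80.0)
    assert prf.f1 == pytest.approx(84.2105263, abs=1e-4)


def test_prf_zero_denominators_are_zero():
    assert PRF(0, 0, 0).precision == 0.0
    assert PRF(0, 3, 2).f1 == 0.0


def test_ner_perfect_prediction(small_corpus):
    corpus, _ = small_corpus
    scores = evaluate_ner(corpus, copy.deepcopy(corpus))
    for prf in scores.values():
        assert (prf.precision, prf.recall, prf.f1) == (100.0, 100.0, 100.0)


def test_ner_forced_arithmetic():
    names = [f"chem{i}" for i in range(10)]
    text = " ".join(names) + " end."
    gold = Corpus([make_doc("1", text,
                            [(n, "Chemical", [f"CHEBI:{i}"])
                             for i, n in enumerate(names)])])
    pred_doc = make_doc("1", text,
                        [(n, "Chemical", [f"CHEBI:{i}"])
                         for i, n in enumerate(names[:8])])
    # three spurious over unannotated words is impossible here; use shifted
    # protein mentions over remaining words
    for j, word in enumerate(["chem8", "chem9", "end"]):
        start = text.index(word) if j < 2 else text.rindex("end")
        from enzchemkit.corpus import EntityMention, Span

        pred_doc.mentions.append(
            EntityMention(f"s{j}", Span(start, start + len(word)), word,
                          "Protein", [f"Q{j}"])
        )
    pred = Corpus([pred_doc])
    overall = evaluate_ner(gold, pred)["Overall"]
    assert overall.precision == pytest.approx(8 / 11 * 100, abs=1e-4)
    assert overall.recall == pytest.approx(80.0)


def test_nen_id_change_counts_fp_and_fn(small_corpus):
    corpus, _ = small_corpus
    pred = copy.deepcopy(corpus)
    victim = None
    participant_ids = {
        (d.pmid, ref)
        for d in pred
        for r in d.relations
        for ref in (r.chem_a, r.chem_b, *r.converters)
    }
    for d in pred:
        for m in d.mentions:
            if (d.pmid, m.mention_id) not in participant_ids:
                victim = m
                break
        if victim:
            break
    victim.identifiers = ["CHEBI:424242"]
    ner_scores = evaluate_ner(corpus, pred)["Overall"]
    nen_scores = evaluate_nen(corpus, pred)["Overall"]
    assert ner_scores.fp == ner_scores.fn == 0
    assert nen_scores.fp == nen_scores.fn == 1


def test_micro_overall_reproducible_from_per_type_counts(small_corpus):
    corpus, _ = small_corpus
    pred, _ = corrupt(corpus, GeneratorConfig(seed=2, drop_rate=0.15,
                                              spurious_rate=0.1))
    scores = evaluate_ner(corpus, pred)
    total = sum((v for k, v in scores.items() if k != "Overall"), PRF(0, 0, 0))
    assert scores["Overall"] == total
    assert 0.0 <= macro_f1(scores) <= 100.0


def test_pmid_mismatch_is_error(small_corpus):
    corpus, _ = small_corpus
    with pytest.raises(ValueError, match="different pmids"):
        evaluate_ner(corpus, Corpus(documents=corpus.documents[:-1]))


# ---------------------------------------------------------------------------
# relation evaluation


def _relation_instances(corpus, arity=2):
    enum = enumerate_binary if arity == 2 else enumerate_ternary
    return [i for d in corpus for i in enum(d)]


def test_relations_perfect_prediction_both_modes(small_corpus):
    corpus, _ = small_corpus
    gold = _relation_instances(corpus)
    pred = _relation_instances(copy.deepcopy(corpus))
    for mode in ("binary", "multiclass"):
        prf = evaluate_relations(gold, pred, arity=2, mode=mode)
        assert prf.f1 == 100.0


def test_indirect_predicted_as_conversion_mode_dependence():
    text = "erythritol is catabolized to dihydroxyacetonephosphate via steps."
    gold_doc = make_doc(
        "163226", text,
        [("erythritol", "Chemical", ["CHEBI:17113"]),
         ("dihydroxyacetonephosphate", "Chemical", ["CHEBI:57642"])],
        [("Indirect_conversion", "m0", "m1", [])],
    )
    pred_doc = copy.deepcopy(gold_doc)
    pred_doc.relations[0].relation_type = "Conversion"
    gold = enumerate_binary(gold_doc)
    pred = enumerate_binary(pred_doc)
    binary = evaluate_relations(gold, pred, mode="binary")
    multi = evaluate_relations(gold, pred, mode="multiclass")
    assert (binary.tp, binary.fp, binary.fn) == (1, 0, 0)
    assert (multi.tp, multi.fp, multi.fn) == (0, 1, 1)


def test_none_instances_never_count_as_tp(conversion_doc):
    gold = enumerate_binary(conversion_doc)
    pred = copy.deepcopy(gold)
    prf = evaluate_relations(gold, pred)
    assert prf.tp == 2  # only the curated relations, not the None pair


def test_duplicate_instance_keys_rejected(conversion_doc):
    gold = enumerate_binary(conversion_doc)
    with pytest.raises(ValueError, match="duplicate"):
        evaluate_relations(gold + [gold[0]], gold)


def test_relations_brute_force_confusion_oracle():
    """Random relabelling of instances scored by exhaustive counting."""
    labels = ["Conversion", "Indirect_conversion", "Non_conversion", NONE_LABEL]
    corpus, _ = generate_corpus(GeneratorConfig(seed=5, n_docs=8))
    gold = _relation_instances(corpus)
    rng = random.Random(13)
    pred = copy.deepcopy(gold)
    for inst in pred:
        inst.gold_label = rng.choice(labels)
    for mode in ("binary", "multiclass"):
        def collapse(l):
            return ("Conversion" if mode == "binary" and l == "Indirect_conversion"
                    else l)

        gold_map = {instance_key(i, 2): collapse(i.gold_label) for i in gold}
        pred_map = {instance_key(i, 2): collapse(i.gold_label) for i in pred}
        tp = fp = fn = 0
        for k, v in pred_map.items():
            if v == NONE_LABEL:
                continue
            if gold_map.get(k) == v:
                tp += 1
            else:
                fp += 1
        for k, v in gold_map.items():
            if v == NONE_LABEL:
                continue
            if pred_map.get(k) != v:
                fn += 1
        got = evaluate_relations(gold, pred, arity=2, mode=mode)
        assert (got.tp, got.fp, got.fn) == (tp, fp, fn)


def test_ternary_evaluation_keys_include_protein(conversion_doc):
    gold = enumerate_ternary(conversion_doc)
    pred = copy.deepcopy(gold)
    prf = evaluate_relations(gold, pred, arity=3)
    assert prf.f1 == 100.0
    # perturbing the protein ID breaks the match
    for inst in pred:
        inst.protein.identifiers = ["P99999"]
    prf = evaluate_relations(gold, pred, arity=3)
    assert prf.tp == 0


# ---------------------------------------------------------------------------
# end-to-end with ontology relaxation


@pytest.fixture()
def serine_pair():
    def build(chem_b_ids):
        text = "serine converts to glycine here."
        return Corpus([
            make_doc("1", text,
                     [("serine", "Chemical", list(chem_b_ids)),
                      ("glycine", "Chemical", ["CHEBI:57305"])],
                     [("Conversion", "m0", "m1", [])])
        ])
    return build


def test_end_to_end_exact_identity(small_corpus):
    corpus, _ = small_corpus
    prf = evaluate_end_to_end(corpus, copy.deepcopy(corpus))
    assert prf.f1 == 100.0


def test_relaxed_matches_one_isa_edge(serine_pair, chem_fixtures):
    gold = serine_pair(["CHEBI:35243"])   # stereoparent
    pred = serine_pair(["CHEBI:33384"])   # L-serine zwitterion, direct child
    onto = chem_fixtures.ontology
    assert evaluate_end_to_end(gold, pred, matching="exact").tp == 0
    assert evaluate_end_to_end(gold, pred, onto, matching="relaxed").tp == 1


def test_relaxed_rejects_two_edge_chain(serine_pair, chem_fixtures):
    gold = serine_pair(["CHEBI:33384"])
    pred = serine_pair(["CHEBI:33709"])   # grandparent, two is_a edges
    prf = evaluate_end_to_end(gold, pred, chem_fixtures.ontology, "relaxed")
    assert prf.tp == 0


def test_relaxed_never_below_exact(small_corpus, chem_fixtures):
    corpus, _ = small_corpus
    pred, _ = corrupt(corpus, GeneratorConfig(seed=9, label_flip_rate=0.3))
    exact = evaluate_end_to_end(corpus, pred, matching="exact")
    relaxed = evaluate_end_to_end(corpus, pred, chem_fixtures.ontology, "relaxed")
    assert relaxed.tp >= exact.tp


def test_relaxed_requires_ontology(small_corpus):
    corpus, _ = small_corpus
    with pytest.raises(ValueError, match="ontology"):
        evaluate_end_to_end(corpus, copy.deepcopy(corpus), None, "relaxed")


def test_mesh_ids_never_relaxed(chem_fixtures):
    gold = Corpus([make_doc("1", "aspirin converts salicylate now.",
                            [("aspirin", "Chemical", ["MESH:D001241"]),
                             ("salicylate", "Chemical", ["CHEBI:30762"])],
                            [("Conversion", "m0", "m1", [])])])
    pred = copy.deepcopy(gold)
    pred.documents[0].mentions[0].identifiers = ["MESH:D020156"]
    prf = evaluate_end_to_end(gold, pred, chem_fixtures.ontology, "relaxed")
    assert prf.tp == 0


def test_ontology_from_obo(tmp_path):
    obo = """format-version: 1.2

[Term]
id: CHEBI:33384
name: L-serine zwitterion
is_a: CHEBI:35243

[Term]
id: CHEBI:35243
name: serine zwitterion
is_a: CHEBI:33709

[Term]
id: CHEBI:33709
name: amino acid zwitterion
"""
    path = tmp_path / "mini.obo"
    path.write_text(obo)
    onto = OntologyGraph.from_obo(path)
    assert onto.adjacent("CHEBI:33384", "CHEBI:35243")
    assert onto.adjacent("CHEBI:35243", "CHEBI:33384")
    assert not onto.adjacent("CHEBI:33384", "CHEBI:33709")
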