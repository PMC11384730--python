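import pytest

from enzchemkit.corpus import (
    AnnotatedDocument,
    Corpus,
    EntityMention,
    Passage,
    RelationRecord,
    Span,
)
from enzchemkit.synthetic import GeneratorConfig, generate_chem_fixtures, generate_corpus


@pytest.fixture(scope="session")
def chem_fixtures():
    return generate_chem_fixtures(seed=0)


@pytest.fixture()
def small_corpus():
    """A 5-document corpus with its generation ledger (seed 1)."""
    return generate_corpus(GeneratorConfig(seed=1, n_docs=5))


def make_doc(pmid, text, mentions, relations=()):
    """One-passage document from (surface, type, ids) span-located in text."""
    ms = []
    cursor = 0
    for i, (surface, etype, ids) in enumerate(mentions):
        start = text.index(surface, cursor)
        ms.append(
            EntityMention(
                mention_id=f"m{i}",
                span=Span(start, start + len(surface)),
                surface=surface,
                entity_type=etype,
                identifiers=list(ids),
            )
        )
        cursor = start + len(surface)
    rs = [
        RelationRecord(
            relation_id=f"r{i}",
            relation_type=rtype,
            chem_a=a,
            chem_b=b,
            converters=list(convs),
        )
        for i, (rtype, a, b, convs) in enumerate(relations)
    ]
    return AnnotatedDocument(
        pmid=pmid, passages=[Passage(0, text)], mentions=ms, relations=rs
    )


@pytest.fixture()
def conversion_doc():
    """One sentence, three chemicals, a protein, two curated Conversions."""
    text = (
        "D-Dopachrome tautomerase converts dopachrome precursor "
        "(D-dopachrome) into dihydroxyindole."
    )
    return make_doc(
        "9480844",
        text,
        [
            ("D-Dopachrome tautomerase", "Protein", ["P30046"]),
            ("dopachrome precursor", "Chemical", ["CHEBI:89788"]),
            ("D-dopachrome", "Chemical", ["CHEBI:89788"]),
            ("dihydroxyindole", "Chemical", ["CHEBI:27404"]),
        ],
        [
            ("Conversion", "m1", "m3", ["m0"]),
            ("Conversion", "m2", "m3", ["m0"]),
        ],
    )
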