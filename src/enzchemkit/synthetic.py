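"""Deterministic synthetic fixtures with self-recorded ground truth.

Generators for toy corpora, lexicons, pH-7.3 maps, ontology fragments,
reaction sets and SMILES tables, so every module is testable without
downloading reference data. Each generator is a pure function of
(seed, config) — the random source is Python's Mersenne Twister
(MT19937), recorded in the ledger, and identical inputs give
byte-identical serialized output.

Corpus sentences come from templates that mirror how abstracts state
conversions ("P converts C1 into C2", catabolism via intermediates,
tested-but-not-converted negatives, and the "respectively" construction
that is a known failure mode of trigger- and attention-based relation
classifiers). The :func:`corrupt` pass plants exact numbers of dropped,
spurious and identifier-substituted annotations plus relation label
flips, so evaluation scores have a closed-form oracle.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field, asdict

from .corpus import (
    AnnotatedDocument,
    Corpus,
    EntityMention,
    Passage,
    RelationRecord,
    Span,
    corpus_statistics,
    validate_corpus,
)
from .evaluation import OntologyGraph
from .nen import Lexicon, Ph73Mapping
from .pairs import RheaReaction

RNG_ALGORITHM = "MT19937"

# name, ChEBI ID, SMILES — a small pool of real small molecules
_CHEMICALS = [
    ("glucose", "CHEBI:17234", "OCC1OC(O)C(O)C(O)C1O"),
    ("pyruvate", "CHEBI:15361", "CC(=O)C(=O)[O-]"),
    ("L-lactate", "CHEBI:16651", "CC(O)C(=O)[O-]"),
    ("ethanol", "CHEBI:16236", "CCO"),
    ("acetaldehyde", "CHEBI:15343", "CC=O"),
    ("acetate", "CHEBI:30089", "CC(=O)[O-]"),
    ("citrate", "CHEBI:16947", "OC(CC(=O)[O-])(CC(=O)[O-])C(=O)[O-]"),
    ("fumarate", "CHEBI:29806", "[O-]C(=O)C=CC(=O)[O-]"),
    ("succinate", "CHEBI:30031", "[O-]C(=O)CCC(=O)[O-]"),
    ("malate", "CHEBI:15595", "OC(CC(=O)[O-])C(=O)[O-]"),
    ("glycerol", "CHEBI:17754", "OCC(O)CO"),
    ("serine", "CHEBI:33384", "OCC([NH3+])C(=O)[O-]"),
    ("glycine", "CHEBI:57305", "[NH3+]CC(=O)[O-]"),
    ("erythritol", "CHEBI:17113", "OCC(O)C(O)CO"),
    ("mesaconate", "CHEBI:30719", "CC(=CC(=O)[O-])C(=O)[O-]"),
    ("oxaloacetate", "CHEBI:16452", "[O-]C(=O)CC(=O)C(=O)[O-]"),
]

_PROTEINS = [
    ("AdhE", "P0A9Q7"),
    ("LdhA", "P52643"),
    ("FumC", "P05042"),
    ("MaeB", "P76558"),
    ("CitA", "P0ABH7"),
    ("GlpK", "P0A6F3"),
    ("SerA", "P0A9T0"),
    ("YhfN", "P37661"),
]


@dataclass
class GeneratorConfig:
    """Study conditions for corpus generation and corruption.

    Relation mix and sentence counts emulate a conversion-dense curated
    abstract set; corruption rates are fractions of eligible items in
    [0, 1] and default to zero (identity).
    """

    seed: int = 0
    n_docs: int = 5
    sentences_per_doc: tuple[int, int] = (3, 5)
    relation_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Conversion": 0.7,
            "Indirect_conversion": 0.2,
            "Non_conversion": 0.1,
        }
    )
    ternary_fraction: float = 0.6
    filler_fraction: float = 0.25
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    id_substitution_rate: float = 0.0
    label_flip_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("ternary_fraction", "filler_fraction", "drop_rate",
                     "spurious_rate", "id_substitution_rate", "label_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ternary_fraction > 0 and not _PROTEINS:
            raise ValueError("ternary relations need protein mentions")


@dataclass
class Ledger:
    """Exact planted counts, self-checked against the emitted corpus."""

    rng_algorithm: str = RNG_ALGORITHM
    n_docs: int = 0
    mentions: dict[str, int] = field(default_factory=dict)
    relations: dict[str, int] = field(default_factory=dict)
    ternary_tuples: dict[str, int] = field(default_factory=dict)
    # corruption pass
    n_dropped: int = 0
    n_spurious: int = 0
    n_id_substituted: int = 0
    n_label_flipped: int = 0
    n_tuples_flipped: int = 0
    n_relations_lost: int = 0

    def ner_counts(self, n_gold_mentions: int) -> tuple[int, int, int]:
        """(tp, fp, fn) for span-level NER implied by the corruption pass."""
        tp = n_gold_mentions - self.n_dropped
        return tp, self.n_spurious, self.n_dropped

    def nen_counts(self, n_gold_mentions: int) -> tuple[int, int, int]:
        tp = n_gold_mentions - self.n_dropped - self.n_id_substituted
        return (
            tp,
            self.n_spurious + self.n_id_substituted,
            self.n_dropped + self.n_id_substituted,
        )


class _Builder:
    """Accumulates one document's text and annotations."""

    def __init__(self, pmid: str):
        self.pmid = pmid
        self.chunks: list[str] = []
        self.pos = 0
        self.mentions: list[EntityMention] = []
        self.relations: list[RelationRecord] = []
        self.sentence_index = -1

    def add_text(self, s: str) -> None:
        self.chunks.append(s)
        self.pos += len(s)

    def add_mention(self, surface: str, etype: str, ids: list[str]) -> EntityMention:
        m = EntityMention(
            mention_id=f"{self.pmid}.m{len(self.mentions)}",
            span=Span(self.pos, self.pos + len(surface)),
            surface=surface,
            entity_type=etype,
            identifiers=list(ids),
        )
        self.mentions.append(m)
        self.add_text(surface)
        return m

    def add_relation(
        self, rtype: str, a: EntityMention, b: EntityMention,
        converters: list[EntityMention] = (),
    ) -> None:
        self.relations.append(
            RelationRecord(
                relation_id=f"{self.pmid}.r{len(self.relations)}",
                relation_type=rtype,
                chem_a=a.mention_id,
                chem_b=b.mention_id,
                converters=[c.mention_id for c in converters],
                sentence_index=self.sentence_index,
            )
        )

    def text(self) -> str:
        return "".join(self.chunks)


def _weighted_choice(rng: random.Random, weights: dict[str, float]) -> str:
    items = sorted(weights.items())
    return rng.choices([k for k, _ in items], [w for _, w in items], k=1)[0]


def _emit_sentence(b: _Builder, rng: random.Random, config: GeneratorConfig,
                   ledger: Ledger) -> None:
    """Append one template sentence with its mentions and relations."""
    b.sentence_index += 1
    chems = rng.sample(_CHEMICALS, 4)
    prot = rng.choice(_PROTEINS)
    if rng.random() < config.filler_fraction:
        kind = rng.choice(["filler_pair", "filler_single"])
    else:
        rtype = _weighted_choice(rng, config.relation_mix)
        ternary = rtype == "Conversion" and rng.random() < config.ternary_fraction
        if ternary and rng.random() < 0.25:
            kind = "respectively"
        elif ternary:
            kind = "ternary"
        else:
            kind = rtype

    def chem(i: int) -> EntityMention:
        name, cid, _ = chems[i]
        m = b.add_mention(name, "Chemical", [cid])
        ledger.mentions["Chemical"] = ledger.mentions.get("Chemical", 0) + 1
        return m

    def protein() -> EntityMention:
        name, acc = prot
        m = b.add_mention(name, "Protein", [acc])
        ledger.mentions["Protein"] = ledger.mentions.get("Protein", 0) + 1
        return m

    def record(rtype: str, a, bm, convs=()) -> None:
        b.add_relation(rtype, a, bm, convs)
        ledger.relations[rtype] = ledger.relations.get(rtype, 0) + 1
        if convs:
            ledger.ternary_tuples[rtype] = (
                ledger.ternary_tuples.get(rtype, 0) + len(convs)
            )

    if kind == "ternary":
        p = protein()
        b.add_text(" converts ")
        c1 = chem(0)
        b.add_text(" into ")
        c2 = chem(1)
        b.add_text(".")
        record("Conversion", c1, c2, [p])
    elif kind == "respectively":
        p = protein()
        b.add_text(" formed ")
        c1 = chem(0)
        b.add_text(" and ")
        c2 = chem(1)
        b.add_text(" from ")
        c3 = chem(2)
        b.add_text(" and ")
        c4 = chem(3)
        b.add_text(", respectively.")
        record("Conversion", c3, c1, [p])
        record("Conversion", c4, c2, [p])
    elif kind == "Conversion":
        c1 = chem(0)
        b.add_text(" is converted to ")
        c2 = chem(1)
        b.add_text(" in cell extracts.")
        record("Conversion", c1, c2)
    elif kind == "Indirect_conversion":
        c1 = chem(0)
        b.add_text(" is catabolized to ")
        c2 = chem(1)
        b.add_text(" through a series of phosphorylated intermediates.")
        record("Indirect_conversion", c1, c2)
    elif kind == "Non_conversion":
        b.add_text("No detectable conversion of ")
        c1 = chem(0)
        b.add_text(" to ")
        c2 = chem(1)
        b.add_text(" was observed.")
        record("Non_conversion", c1, c2)
    elif kind == "filler_pair":
        b.add_text("Samples of ")
        chem(0)
        b.add_text(" and ")
        chem(1)
        b.add_text(" were analyzed by chromatography.")
    else:  # filler_single
        b.add_text("The assay buffer contained ")
        chem(0)
        b.add_text(" at saturating concentration.")


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, Ledger]:
    """Generate a schema-valid toy corpus and its exact count ledger.

    The ledger is cross-checked against :func:`corpus_statistics` before
    returning, so ledger arithmetic and emitted annotations cannot drift.
    """
    rng = random.Random(config.seed)
    ledger = Ledger(n_docs=config.n_docs)
    corpus = Corpus(provenance=f"synthetic corpus (seed={config.seed})")
    for d in range(config.n_docs):
        pmid = str(9000001 + 7 * config.seed + d)
        b = _Builder(pmid)
        b.sentence_index = -1
        title = f"Enzymatic conversion study {d + 1}."
        n_sents = rng.randint(*config.sentences_per_doc)
        for i in range(n_sents):
            if i:
                b.add_text(" ")
            _emit_sentence(b, rng, config, ledger)
        abstract = b.text()
        doc = AnnotatedDocument(
            pmid=pmid,
            passages=[
                Passage(offset=0, text=title, infons={"type": "title"}),
                Passage(offset=len(title) + 1, text=abstract,
                        infons={"type": "abstract"}),
            ],
        )
        shift = len(title) + 1
        for m in b.mentions:
            m.span = Span(m.span.start + shift, m.span.end + shift)
            doc.mentions.append(m)
        doc.relations.extend(b.relations)
        corpus.documents.append(doc)
    validate_corpus(corpus)
    _self_check(corpus, ledger)
    return corpus, ledger


def _self_check(corpus: Corpus, ledger: Ledger) -> None:
    stats = corpus_statistics(corpus)
    for etype, n in ledger.mentions.items():
        assert stats.entity_mentions[etype] == n, (etype, n, stats.entity_mentions)
    for rtype, n in ledger.relations.items():
        assert stats.binary_pairs[rtype] == n
    for rtype, n in ledger.ternary_tuples.items():
        assert stats.ternary_tuples[rtype] == n


# ---------------------------------------------------------------------------
# Corruption


def _count(rate: float, n: int) -> int:
    return min(n, int(round(rate * n)))


def corrupt(corpus: Corpus, config: GeneratorConfig) -> tuple[Corpus, Ledger]:
    """Plant a known number of annotation errors into a copy of a corpus.

    Drops, identifier substitutions and spurious mentions target mentions
    that do not participate in relations, so the relation-instance keys
    stay intact and NER/NEN/RE scores all have closed-form oracles.
    Requested counts exceeding the eligible pool are capped (recorded in
    the ledger as the actual numbers). Relations whose participants were
    nevertheless dropped are removed and counted as lost.
    """
    rng = random.Random(config.seed + 0x5EED)
    ledger = Ledger(n_docs=len(corpus))
    out = Corpus(provenance=corpus.provenance + " [corrupted]")

    all_mentions: list[tuple[str, EntityMention]] = []
    participants: set[tuple[str, str]] = set()
    for doc in corpus:
        for r in doc.relations:
            for ref in (r.chem_a, r.chem_b, *r.converters):
                participants.add((doc.pmid, ref))
        for m in doc.mentions:
            all_mentions.append((doc.pmid, m))
    eligible = [
        (pmid, m) for pmid, m in all_mentions if (pmid, m.mention_id) not in participants
    ]
    rng.shuffle(eligible)

    n_drop = _count(config.drop_rate, len(all_mentions))
    n_sub = _count(config.id_substitution_rate, len(all_mentions))
    if n_drop + n_sub > len(eligible):
        import warnings

        warnings.warn(
            f"corruption rates exceed {len(eligible)} eligible mentions; capped",
            stacklevel=2,
        )
        n_drop = min(n_drop, len(eligible))
        n_sub = min(n_sub, len(eligible) - n_drop)
    to_drop = {(p, m.mention_id) for p, m in eligible[:n_drop]}
    to_sub = {(p, m.mention_id) for p, m in eligible[n_drop : n_drop + n_sub]}
    n_spurious = _count(config.spurious_rate, len(all_mentions))

    used_ids = {i for _, m in all_mentions for i in m.identifiers}
    fresh = (f"CHEBI:99{i:04d}" for i in range(10000) if f"CHEBI:99{i:04d}" not in used_ids)

    n_relations = sum(len(d.relations) for d in corpus)
    n_flip = _count(config.label_flip_rate, n_relations)
    flip_keys = set(
        rng.sample(
            [(d.pmid, r.relation_id) for d in corpus for r in d.relations],
            n_flip,
        )
    )

    spurious_budget = n_spurious
    for doc in corpus:
        new_doc = AnnotatedDocument(
            pmid=doc.pmid,
            passages=[Passage(p.offset, p.text, dict(p.infons)) for p in doc.passages],
            infons=dict(doc.infons),
        )
        kept_ids = set()
        occupied: list[Span] = [m.span for m in doc.mentions]
        for m in doc.mentions:
            key = (doc.pmid, m.mention_id)
            if key in to_drop:
                ledger.n_dropped += 1
                continue
            ids = list(m.identifiers)
            if key in to_sub:
                ids = [next(fresh)]
                ledger.n_id_substituted += 1
            new_doc.mentions.append(
                EntityMention(
                    mention_id=m.mention_id,
                    span=m.span,
                    surface=m.surface,
                    entity_type=m.entity_type,
                    identifiers=ids,
                    infons=dict(m.infons),
                )
            )
            kept_ids.add(m.mention_id)
        if spurious_budget:
            added = _plant_spurious(new_doc, doc, occupied, spurious_budget, rng)
            ledger.n_spurious += added
            spurious_budget -= added
        for r in doc.relations:
            refs = (r.chem_a, r.chem_b, *r.converters)
            if any(ref not in kept_ids for ref in refs):
                ledger.n_relations_lost += 1
                continue
            rtype = r.relation_type
            if (doc.pmid, r.relation_id) in flip_keys:
                rtype = (
                    "Non_conversion" if rtype != "Non_conversion" else "Conversion"
                )
                ledger.n_label_flipped += 1
                ledger.n_tuples_flipped += len(r.converters)
            new_doc.relations.append(
                RelationRecord(
                    relation_id=r.relation_id,
                    relation_type=rtype,
                    chem_a=r.chem_a,
                    chem_b=r.chem_b,
                    converters=list(r.converters),
                    sentence_index=r.sentence_index,
                    infons=dict(r.infons),
                )
            )
        out.documents.append(new_doc)
    validate_corpus(out)
    return out, ledger


_SPURIOUS_WORD = re.compile(r"[A-Za-z]{4,}")


def _plant_spurious(
    new_doc: AnnotatedDocument,
    gold_doc: AnnotatedDocument,
    occupied: list[Span],
    budget: int,
    rng: random.Random,
) -> int:
    """Add up to ``budget`` mentions over unannotated words of this doc."""
    text = gold_doc.text()
    candidates = []
    for m in _SPURIOUS_WORD.finditer(text):
        span = Span(m.start(), m.end())
        if not any(span.overlaps(o) for o in occupied):
            candidates.append(span)
    rng.shuffle(candidates)
    added = 0
    for span in candidates[:budget]:
        etype = "Chemical" if added % 2 == 0 else "Protein"
        new_doc.mentions.append(
            EntityMention(
                mention_id=f"{gold_doc.pmid}.spurious{added}",
                span=span,
                surface=text[span.start : span.end],
                entity_type=etype,
                identifiers=[f"CHEBI:98{added:03d}" if etype == "Chemical" else f"Q9{added:04d}"],
            )
        )
        occupied.append(span)
        added += 1
    return added


# ---------------------------------------------------------------------------
# Chemistry fixtures


@dataclass
class ChemFixtures:
    """Toy lexicons, pH map, ontology fragment, reactions, SMILES table."""

    lexicons: dict[str, Lexicon]
    ph73: Ph73Mapping
    ontology: OntologyGraph
    reactions: list[RheaReaction]
    smiles: dict[str, str]
    gold_abbreviations: dict[str, str]


def generate_chem_fixtures(seed: int = 0) -> ChemFixtures:
    """Fixtures satisfying every module invariant, planted by construction.

    Includes: a step-4 pivot case (a term only in the MeSH-style lexicon
    sharing an InChIKey with a ChEBI entry), a 'single' cross-reference
    case, an idempotent pH-7.3 map with an acid-to-anion row, an acyclic
    three-node is_a chain for relaxed matching, a transport reaction
    (identical ID on both sides), and parseable SMILES for every compound.
    """
    rng = random.Random(seed)

    chebi = Lexicon("CHEBI")
    for name, cid, smi in _CHEMICALS:
        chebi.add(cid, name)
        chebi.add_xref(cid, "SMILES", smi)
    chebi.add("CHEBI:17234", "D-glucose")
    chebi.add("CHEBI:16651", "Lactate")  # step-2 case for "lactate,"
    chebi.add("CHEBI:15361", "pyruvates")  # step-3 case: stem match
    chebi.add("CHEBI:35183", "triphenyl phosphate")
    chebi.add_xref("CHEBI:15347", "InChIKey", "CSCPPACGZOOCGX-UHFFFAOYSA-N")
    chebi.add("CHEBI:15347", "propan-2-one")  # acetone, ChEBI-side name only

    mesh = Lexicon("MESH")
    mesh.add("MESH:D000096", "acetone")  # pivot via shared InChIKey
    mesh.add_xref("MESH:D000096", "InChIKey", "CSCPPACGZOOCGX-UHFFFAOYSA-N")
    mesh.add("MESH:D005947", "dextrose")  # 'single' xref to ChEBI glucose
    mesh.add_xref("MESH:D005947", "CHEBI", "CHEBI:17234")
    mesh.add("MESH:D008055", "lipid peroxides")

    # pH-7.3 map: acid forms to anions, plus identity rows; idempotent.
    ph73 = Ph73Mapping(
        {
            "CHEBI:15366": "CHEBI:30089",  # acetic acid -> acetate
            "CHEBI:30089": "CHEBI:30089",
            "CHEBI:18012": "CHEBI:29806",  # fumaric acid -> fumarate
            "CHEBI:29806": "CHEBI:29806",
            "CHEBI:17234": "CHEBI:17234",
        }
    )

    # is_a chain: L-serine zwitterion -> serine zwitterion -> amino acid
    ontology = OntologyGraph.from_edges(
        [
            ("CHEBI:33384", "CHEBI:35243"),
            ("CHEBI:35243", "CHEBI:33709"),
            ("CHEBI:57305", "CHEBI:33709"),
        ]
    )

    water = "CHEBI:15377"
    reactions = [
        RheaReaction(
            "RHEA:10000",
            [("left", "CHEBI:17234", 1), ("left", water, 1),
             ("right", "CHEBI:15361", 2)],
        ),
        RheaReaction(
            "RHEA:10001",
            [("left", "CHEBI:16236", 1), ("right", "CHEBI:15343", 1),
             ("right", water, 1)],
        ),
        RheaReaction(
            "RHEA:10002",
            [("left", "CHEBI:29806", 1), ("left", water, 1),
             ("right", "CHEBI:15595", 1)],
        ),
        # transport reaction: the same compound on both sides
        RheaReaction(
            "RHEA:10003",
            [("left", "CHEBI:30089", 1), ("right", "CHEBI:30089", 1)],
        ),
    ]

    smiles = {cid: smi for _, cid, smi in _CHEMICALS}
    smiles["CHEBI:15377"] = "O"
    smiles["CHEBI:15347"] = "CC(C)=O"
    smiles["CHEBI:16183"] = "C"  # methane

    gold_abbreviations = {
        "TPP": "triphenyl phosphate",
        "D-dopachrome": "2-carboxy-2,3-dihydroindole-5,6-quinone",
    }

    return ChemFixtures(
        lexicons={"CHEBI": chebi, "MESH": mesh},
        ph73=ph73,
        ontology=ontology,
        reactions=reactions,
        smiles=smiles,
        gold_abbreviations=gold_abbreviations,
    )


def random_lexicons(
    rng: random.Random, n_terms: int = 30
) -> tuple[dict[str, Lexicon], list[str]]:
    """Randomized lexicon pair for sieve brute-force checks.

    Terms are planted so that every sieve step (and no-match) occurs:
    exact synonyms, case/punctuation variants, plural forms, and
    cross-lexicon entries linked by 'single' xrefs or shared InChIKeys.
    Returns the lexicons and the query terms to probe.
    """
    target = Lexicon("CHEBI")
    other = Lexicon("MESH")
    lexicons = {"CHEBI": target, "MESH": other}
    queries: list[str] = []
    consonants = "bcdfglmnprst"
    vowels = "aeiou"

    def word() -> str:
        return "".join(
            rng.choice(consonants) + rng.choice(vowels) for _ in range(rng.randint(2, 4))
        )

    for i in range(n_terms):
        base = word() + rng.choice(["ate", "ol", "ine", "ose"])
        cid = f"CHEBI:{1000 + i}"
        mid = f"MESH:D{1000 + i}"
        case = rng.randrange(6)
        if case == 0:  # step 1: exact synonym in target
            target.add(cid, base)
            queries.append(base)
        elif case == 1:  # step 2: stored capitalized, queried with punctuation
            target.add(cid, base.capitalize())
            queries.append(base + ",")
        elif case == 2:  # step 3: stored plural, queried singular (or reverse)
            target.add(cid, base + "s")
            queries.append(base)
        elif case == 3:  # step 4: only in other lexicon, 'single' xref
            other.add(mid, base)
            other.add_xref(mid, "CHEBI", cid)
            target.add(cid, word())  # unrelated synonym so cid exists
            queries.append(base.upper())
        elif case == 4:  # step 4/5 pivot: shared InChIKey
            key = f"KEY{i:04d}-UHFFFAOYSA-N"
            other.add(mid, base)
            other.add_xref(mid, "InChIKey", key)
            target.add(cid, word())
            target.add_xref(cid, "InChIKey", key)
            queries.append(base + "s")
        else:  # no match anywhere
            queries.append(base + "xqz")
    return lexicons, queries
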