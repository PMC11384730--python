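# enzchemkit

A toolkit for corpora of enzyme-chemistry relation annotations: PubMed
abstracts in which chemical and protein mentions carry database identifiers
(ChEBI/MeSH for chemicals, UniProtKB accessions for proteins) and chemical
conversions are curated as relations between mention pairs — optionally with
enzyme "Converter" roles forming ternary (enzyme, substrate, product)
tuples. It is written for biocurators and NLP researchers who build or
evaluate pipelines that extract enzyme functions from literature and feed
reaction knowledgebases such as Rhea and UniProtKB.

The package covers every deterministic computation around such a corpus:

* **Corpus model and BioC I/O** (`corpus`, `bioc`) — a lossless reader and
  writer for PubTator-style BioC XML, schema validation, summary statistics
  (mention/pair/tuple counts and unique-ID counts), and inter-annotator
  agreement computed as the F1 between two annotation sets.
* **IOB2 encoding** (`ner`) — sentence/token segmentation and conversion
  between mention annotations and sequence labels over the five-label set
  {O-Reaction, B-Chemical, I-Chemical, B-Gene, I-Gene}, as used by
  all-in-one sequence taggers.
* **Sieve normalization** (`nen`) — chemical mention to identifier mapping
  via abbreviation resolution plus a five-step candidate lookup of
  decreasing precision (exact → case/punctuation-normalized → stemmed →
  cross-lexicon by direct cross-reference → cross-lexicon by shared
  InChIKey/SMILES/CAS), document-level disambiguation, and pH-7.3 ChEBI
  remapping.
* **Relation instances** (`instances`) — enumeration of binary chemical
  pairs and ternary enzyme tuples at sentence level with synthesized
  "None" negatives, tagged input rendering (`[Reaction]`, `<C1>`, `<C2>`,
  `<P>` markers), and a deterministic trigger-word baseline classifier.
* **Evaluation** (`evaluation`) — micro-averaged P/R/F1 contracts for NER,
  NER+NEN, binary/multiclass relation classification, and end-to-end runs
  with exact or relaxed ChEBI matching (one `is_a` edge in the ontology).
* **Chemical pairs** (`pairs`) — reference-pair extraction from reaction
  participant lists (top-frequency compound removal, all-pairs enumeration,
  transport-pair removal), prediction normalization, overlap comparison,
  the atom-conservation metric, and a differential-reaction-fingerprint
  distance adapter.
* **Synthetic fixtures** (`synthetic`) — seeded generators for corpora,
  lexicons, pH maps, ontology fragments, reactions and SMILES tables with
  self-recorded ground-truth ledgers, so everything is testable offline.

## The core quantities

Evaluation reports precision, recall and F1 as percentages,

    P = 100·TP/(TP+FP),  R = 100·TP/(TP+FN),  F1 = 2PR/(P+R),

with task-specific match keys (spans and types for NER; plus identifier
sets for NEN; plus relation types, pair spans/IDs and — for ternary tuples
— the protein span/ID for relation extraction). Atom conservation between
the two members of a chemical pair is

    % atom conservation = ½ · (n_MCS/n_L + n_MCS/n_R) · 100,

where n_MCS is the atom count of the maximum common substructure of the two
molecules after reducing all bonds to single bonds, and n_L, n_R are their
heavy-atom counts. Curated substrate/product pairs conserve most of their
atoms, so the metric filters noise out of text-mined pairs.

## Worked example

```python
from enzchemkit import (GeneratorConfig, generate_corpus, corpus_statistics,
                        enumerate_binary, render, atom_conservation)

corpus, ledger = generate_corpus(GeneratorConfig(seed=1, n_docs=5))
stats = corpus_statistics(corpus)
print(stats.entity_mentions)   # {'All': 51, 'Chemical': 43, 'Protein': 8, ...}
print(stats.binary_pairs)      # {'All': 15, 'Conversion': 11,
                               #  'Indirect_conversion': 1, 'Non_conversion': 3}

doc = corpus.documents[0]
inst = enumerate_binary(doc)[0]
print(inst.gold_label)         # Conversion
print(render(inst, doc.text()))
# [Reaction] YhfN converts <C1>L-lactate</C1> into <C2>acetaldehyde</C2>. ...

print(round(atom_conservation("CCO", "C").percent, 2))   # 66.67
```

The statistics equal the generator's own ledger (51 mentions, 15 curated
pairs planted for seed 1); the rendered sentence wraps exactly the two
chemical surfaces of the instance; and the ethanol/methane pair shares one
carbon of ethanol's three heavy atoms, giving ½·(1/3 + 1/1)·100 = 66.67%.

A command-line interface mirrors the library:

```
enzchemkit fixtures --seed 1 --out fx/
enzchemkit stats fx/corpus.bioc.xml --json
enzchemkit validate fx/corpus.bioc.xml
enzchemkit iaa a.xml b.xml --level entity
enzchemkit convert-ner fx/corpus.bioc.xml -o ner.tsv
enzchemkit make-instances fx/corpus.bioc.xml --arity 3 -o instances.tsv
enzchemkit evaluate gold.xml pred.xml --task nen
enzchemkit pairs extract-rhea fx/reactions.tsv --top-k 1
enzchemkit atomcons "CCO" "C"
```

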