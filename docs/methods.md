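# Methods

This note documents the models, contracts and design choices behind
enzchemkit, in the spirit of a package's methods documentation: what each
computation assumes, which parameters matter, and what the synthetic test
conditions do and do not show about real corpora.

## Corpus model

A corpus is a list of documents; a document is a list of passages (title
and abstract) plus mention and relation annotations. Character offsets are
0-based and half-open over the concatenated document text with BioC passage
offsets honoured — gaps between passages are padded with spaces so
annotation offsets index directly into the text. Five entity types are
modelled (Chemical, Protein, Domain, MutantEnzyme, Coreference); the last
three are curated only when they participate in conversions, so they are
excluded from NER encoding and from all evaluation by default (an
`include_auxiliary` flag re-includes them, mapped to the Gene class, for
experimentation). Three relation types exist on chemical pairs —
Conversion (substrate/product pairing), Indirect_conversion
(interconversion via unstated intermediates), Non_conversion
(experimentally excluded interconversion) — plus enzyme Converter roles
that turn a pair into ternary tuples. The "None" label exists only during
instance enumeration and is never serialized.

Discontinuous BioC annotations (multiple `location` elements) are split
into separate mentions sharing identifiers; this is the safest lossless
reading and the released-style corpora we target contain none. Relation
role infon keys (`Chemical1`/`Chemical2`/`Converter`) are configurable
through a dialect object because serialization keys are not part of any
printed schema.

### Statistics and unique-ID counting

Raw counts tally every occurrence. Unique counts deduplicate by
identifier: a composite mention (several IDs) contributes each ID once to
the per-type unique tally; pairs deduplicate as unordered pairs of
canonical ID sets; ternary tuples as (pair, converter-ID-set). This choice
keeps each block of the summary table additive (All = sum of subtypes for
raw counts). Where reference statistics are reported for released corpora,
the convention used by their curators for composite mentions is not
documented; ours is recorded here and exercised by tests.

### Inter-annotator agreement

Agreement between two curation copies is reported as the F1 between the
two annotation sets — at entity level a match requires identical span,
type and identifier set; at pair level identical chemical spans/ID sets
plus the relation type. F1 is symmetric in the two sets, so neither copy
is privileged. Published agreement figures for comparable corpora do not
state their formula; we fix F1 and document it rather than guessing
percent agreement.

## Segmentation and IOB2 encoding

The segmenter is a deterministic regex tokenizer (`\w+|[^\w\s]`) with a
sentence splitter on terminal punctuation followed by an upper-case or
digit start, with a short abbreviation stoplist. The contract — every
non-whitespace character in exactly one token, strictly increasing spans,
sentences never splitting tokens — is what downstream code relies on; any
conformant tokenizer can be swapped in. A consequence of the conservative
splitter is that a sentence beginning with a lower-case chemical name does
not open a new sentence; the instance enumeration is self-consistent under
any conformant segmentation because relation labels attach by mention
identity, not sentence ordinals.

Encoding maps Chemical → B-/I-Chemical and Protein → B-/I-Gene, everything
else to the task-specific outside label O-Reaction. Mentions not aligned
to token boundaries snap outward to the covering tokens (maximizing the
recalled surface) and are logged. Decoding repairs an ill-formed I-X after
O as B-X with a warning. Encode/decode is an inverse pair on
boundary-aligned mentions, verified property-style at scale.

## Normalization sieve

Lookup proceeds through five steps of decreasing precision and stops at
the first non-empty candidate set: (1) exact surface in the target
lexicon; (2) the processed form — lower-cased with all non-alphanumerics
stripped — against processed synonyms; (3) the stemmed processed form
against stemmed synonyms; (4) the processed form across all registered
lexicons, mapped to the target; (5) the stemmed form across all lexicons,
mapped to the target. Design choices that were genuinely open:

* **Stemmer**: a small Porter-style suffix stemmer (plural and participle
  rules) named `porter-lite` in configuration, so results are labelled
  with the stemmer used. Chemical synonymy rarely needs deeper stemming,
  and a fixed tiny rule set keeps the sieve deterministic and auditable.
* **Both sides stemmed** in step 3: stemming only the query could never
  match a stored plural, which is the common case in chemical lexicons.
* **Cross-lexicon mapping**: direct ID cross-references ('single') are
  preferred over structural-key pivots; pivots try InChIKey, then SMILES,
  then CAS — InChIKey is the most collision-resistant of the three.
* **Abbreviation expansion** uses the classical parenthetical
  short/long-form alignment heuristic (innermost parentheses first; a
  parenthetical too long to be a short form is treated as the long form of
  the preceding token). Expansion is conservative: the long form is used
  only when the short form itself produced no hit, so curated chemical
  acronyms are never regressed. An external abbreviation tool can be
  plugged in by passing its output as the abbreviation map.
* **Post-processing**: the non-chemical filter is a configurable stoplist
  of processed forms (shipped empty); ambiguous mentions keep the
  candidate supported by an unambiguous mention in the same document
  (same processed form preferred), and residual ties break to the lowest
  numeric ID with a warning — an arbitrary but deterministic rule.

The pH-7.3 map (ChEBI ID → ChEBI ID of the major protonation state at
pH 7.3, the form used by reaction knowledgebases) is applied with
pass-through for unknown IDs and is idempotent by construction of the
table (targets map to themselves).

## Relation instances

Sentence-level task definition: every unordered pair of chemical mentions
co-occurring in a sentence is a binary instance; the cross product of
in-sentence protein mentions with in-sentence chemical pairs gives ternary
instances, each occurrence of a repeated protein being a distinct
instance. Gold labels come from curated relations; everything else is
None — including tuples whose pair is curated but whose protein is not a
Converter of that relation. Curated relations whose mentions straddle
sentences are excluded from enumeration (logged) but kept in the corpus;
the schema allows such evidence, the sentence-level task does not use it.
Coreference mentions participate through their normalized identifiers
(chemical-namespaced IDs make them chemicals, otherwise proteins).

Rendering prefixes the task tag and wraps the pair (and protein) in
boundary markers, inserting right-to-left so offsets stay valid; marker
text is configurable because only the protein markers (`<P>`, `</P>`) and
task tag are fixed by convention — chemical-pair markers default to
`<C1>`/`<C2>`. The trigger-word baseline classifier exists so evaluation
and end-to-end plumbing can run without any trained model; its known
failure modes (e.g. "respectively" constructions pairing all listed
substrates with all products) are deliberately present in the synthetic
templates.

## Evaluation

All scores are micro-averaged percentages from hashable match keys; a
macro-averaged F1 over types is also emitted for the entity tasks. F1 is
defined as 0 when TP = 0 (avoiding NaN). In binary classification mode,
Conversion and Indirect_conversion collapse into one positive class while
Non_conversion stays distinct; None instances are negatives on both sides
and never true positives. Relaxed end-to-end matching allows a chemical's
ChEBI ID set to match through a one-to-one pairing where each pair is
equal or exactly one `is_a` edge apart (parent or child) in the ontology;
matching between the gold and predicted relation sets then uses maximum
bipartite matching so no prediction is double-counted. MeSH and other
namespaces always require exact equality — only the ChEBI ontology
licenses relaxation. Relaxation can only add matches, so relaxed TP ≥
exact TP on any input (tested as an invariant).

## Chemical pairs and atom conservation

Reference pairs: the top-k most reaction-frequent compounds (default
k = 100; frequency is the number of reactions containing the compound,
computed on the participant lists as given — the reaction knowledgebase
already stores pH-7.3 forms) are removed, then all unordered pairs of the
remaining participants within each reaction are enumerated. "All pairs"
is read literally (within- and cross-side); a `cross_side_only` switch
covers the stricter substrate-vs-product reading. Identical-ID pairs
(transport reactions) are removed. Ties at rank k include every tied
compound, logged, so the exclusion set is deterministic.

Predicted pairs are normalized in a fixed, observable order — pH-7.3
mapping, exclusion filter, identical-ID removal, deduplication — with
stage-wise removal counts that must reconcile with |in| − |out| (asserted
at run time).

Atom conservation uses heavy atoms only (hydrogens implicit), standard
MCS practice: both molecules are reduced to single-bond graphs, the MCS is
computed with permissive ring fusion and order-insensitive bond
comparison, and the percentage ½(n_MCS/n_L + n_MCS/n_R)·100 is returned.
When no common bond exists (e.g. methane against anything) the largest
common fragment is a single shared element. The default filter threshold
for text-mined pairs is 79.76%, the mean conservation reported over
structure-resolvable reference pairs; it is a configurable constant, not a
computed quantity here. The fingerprint-distance interface is an adapter:
any encoder mapping reaction SMILES to binary vectors can be injected
(members are canonically ordered first, making the distance
order-invariant), and without a provider the feature raises a clear error
rather than approximating.

## Synthetic study conditions

The generator emits abstracts from a fixed pool of real small molecules
(with ChEBI IDs and SMILES) and enzyme names (with UniProtKB accessions),
using sentence templates for ternary conversions, enzyme-less conversions,
indirect conversions via intermediates, tested non-conversions, the
"respectively" two-pair construction, and relation-free filler. Defaults:
5 documents, 3–5 sentences each, relation mix 70/20/10 across
Conversion/Indirect_conversion/Non_conversion (matching the strong
dominance of direct conversions and the rarity of non-conversions in
curated data), ternary fraction 0.6, filler fraction 0.25. The random
source is Python's MT19937, recorded in the ledger; generation is a pure
function of (seed, config) and serialized output is byte-identical across
runs.

The corruption pass plants exact numbers of dropped, spurious and
ID-substituted mentions plus relation label flips, recording actual counts
in a ledger; drops and substitutions target mentions outside relations so
NER, NEN and RE scores all have closed-form oracles simultaneously.
Spurious mentions are placed over unannotated words, never colliding with
gold spans. Requested counts exceeding the eligible pool are capped with a
warning and the ledger reflects reality.

What passing these tests shows: the contracts — round-trip identity, sieve
ordering, closed-form scoring, filter-order accounting — hold exactly at
realistic annotation densities. What they do not show: performance of any
statistical tagger or classifier on real text (training and inference are
out of scope), robustness to the full lexical variety of PubMed abstracts,
or the behaviour of the sieve on production-size lexicons with millions of
synonyms.

## Problem sizes and numerical choices

The test suite and the acceptance script run the round-trip and
oracle checks over 500–1000 generated corpora, the sieve comparison over
640 randomized terms, and the MCS oracle over all pairs of a ten-molecule
battery (the exhaustive subgraph oracle enumerates connected edge
subsets, so it is kept to molecules of ≤6 heavy atoms); these sizes give
exact, deterministic comparisons while keeping a full run in seconds. MCS
search carries a 30-second timeout as a safety net, never reached at
these sizes. All percentages are exact rational arithmetic in floating
point; no tolerance looser than printing precision is needed anywhere
except F1 comparisons, which use standard floating-point closeness.

## Known limitations

* The BioC reader accepts only the PubTator-style infon dialect described
  here (type/identifier keys); other BioC flavours need a dialect object.
* The sentence splitter is deliberately conservative; corpora with
  unusual punctuation may under-split, which is harmless for instance
  enumeration but changes sentence ordinals.
* Protein normalization is bookkeeping only — mapping protein mentions to
  UniProtKB accessions from text is out of scope, reflecting the poor
  state of the art for this subtask.
* The trigger-word baseline is a plumbing device, not a model; its scores
  on any real corpus are expected to be poor.
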