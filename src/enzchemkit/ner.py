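"""Sentence/token segmentation and IOB2 label-sequence conversion.

NER over enzyme-chemistry abstracts is framed as sequence labelling: text
is a token sequence x = (x1..xn) and the goal is a label sequence
y = (y1..yn) over the closed set ``LABELS``. Following the all-in-one
tagging scheme, the outside label is task-specific ("O-Reaction") and
protein mentions map to the "Gene" entity class, giving five labels:
O-Reaction, B-Chemical, I-Chemical, B-Gene, I-Gene.

The segmenter is a deterministic regex tokenizer. The segmentation
contract — every non-whitespace character belongs to exactly one token,
token spans strictly increasing, sentence boundaries never split tokens —
is what downstream code relies on; any conformant tokenizer can be
substituted.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

from .corpus import AnnotatedDocument, EntityMention, Span

log = logging.getLogger(__name__)

OUTSIDE = "O-Reaction"
LABELS = (OUTSIDE, "B-Chemical", "I-Chemical", "B-Gene", "I-Gene")

#: entity type -> IOB2 class for the types included in NER encoding
_TYPE_TO_CLASS = {"Chemical": "Chemical", "Protein": "Gene"}
#: types excluded from encoding by default (not systematically curated)
AUXILIARY_TYPES = ("Domain", "MutantEnzyme", "Coreference")
_CLASS_TO_TYPE = {"Chemical": "Chemical", "Gene": "Protein"}

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
# Sentence boundary: terminal punctuation, whitespace, then an upper-case
# letter, digit or opening bracket. Common abbreviations are not split.
_SENT_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9(\"'])")
_NO_SPLIT_BEFORE = re.compile(r"(?:\b(?:e\.g|i\.e|cf|vs|et al|Fig|ca)\.)$")


@dataclass(frozen=True)
class Token:
    surface: str
    span: Span


@dataclass
class TokenSequence:
    """One sentence as ordered tokens with absolute character spans."""

    tokens: list[Token]
    sentence_index: int

    def span(self) -> Span:
        return Span(self.tokens[0].span.start, self.tokens[-1].span.end)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class LabelSequence:
    """IOB2 labels aligned 1:1 with a :class:`TokenSequence`."""

    labels: list[str]
    sentence_index: int

    def __post_init__(self) -> None:
        for lab in self.labels:
            if lab not in LABELS:
                raise ValueError(f"label {lab!r} outside the label set")

    def __len__(self) -> int:
        return len(self.labels)


class MentionCollisionError(ValueError):
    """Raised when overlapping mentions cannot be jointly encoded."""


def sentence_spans(text: str) -> list[Span]:
    """Character spans of sentences, trimmed of surrounding whitespace."""
    bounds = [0]
    for m in _SENT_RE.finditer(text):
        if _NO_SPLIT_BEFORE.search(text[: m.start()]):
            continue
        bounds.append(m.end())
    bounds.append(len(text))
    spans = []
    for s, e in zip(bounds, bounds[1:]):
        chunk = text[s:e]
        ls = len(chunk) - len(chunk.lstrip())
        rs = len(chunk) - len(chunk.rstrip())
        if s + ls < e - rs:
            spans.append(Span(s + ls, e - rs))
    return spans


def segment(text: str) -> list[TokenSequence]:
    """Split document text into sentences of tokens with absolute spans.

    Empty or all-whitespace text yields an empty list.
    """
    sequences = []
    for i, sent in enumerate(sentence_spans(text)):
        tokens = [
            Token(m.group(), Span(sent.start + m.start(), sent.start + m.end()))
            for m in _TOKEN_RE.finditer(text[sent.start : sent.end])
        ]
        if tokens:
            sequences.append(TokenSequence(tokens=tokens, sentence_index=len(sequences)))
    return sequences


def _covering_tokens(tokens: list[Token], span: Span) -> list[int]:
    return [i for i, t in enumerate(tokens) if t.span.overlaps(span)]


def encode_iob2(
    doc: AnnotatedDocument,
    token_seqs: list[TokenSequence] | None = None,
    include_auxiliary: bool = False,
) -> list[LabelSequence]:
    """Encode a document's mentions as IOB2 label sequences.

    Chemical mentions become B-/I-Chemical and Protein mentions B-/I-Gene.
    Domain, MutantEnzyme and Coreference mentions are excluded unless
    ``include_auxiliary`` is set, in which case they map to the Gene class.
    Mentions not aligned to token boundaries are snapped outward to the
    covering tokens (logged). Overlapping encodable mentions raise
    :class:`MentionCollisionError`.
    """
    if token_seqs is None:
        token_seqs = segment(doc.text())
    label_seqs = [
        LabelSequence(labels=[OUTSIDE] * len(ts), sentence_index=ts.sentence_index)
        for ts in token_seqs
    ]
    owner: dict[tuple[int, int], str] = {}
    for m in doc.mentions:
        cls = _TYPE_TO_CLASS.get(m.entity_type)
        if cls is None:
            if not include_auxiliary or m.entity_type not in AUXILIARY_TYPES:
                continue
            cls = "Gene"
        for si, ts in enumerate(token_seqs):
            idxs = _covering_tokens(ts.tokens, m.span)
            if not idxs:
                continue
            first, last = ts.tokens[idxs[0]], ts.tokens[idxs[-1]]
            if first.span.start != m.span.start or last.span.end != m.span.end:
                log.info(
                    "pmid %s: mention %s snapped outward to [%d, %d)",
                    doc.pmid, m.mention_id, first.span.start, last.span.end,
                )
            for j, idx in enumerate(idxs):
                if (si, idx) in owner:
                    raise MentionCollisionError(
                        f"pmid {doc.pmid}: mentions {owner[(si, idx)]} and "
                        f"{m.mention_id} overlap on token {ts.tokens[idx].surface!r}"
                    )
                owner[(si, idx)] = m.mention_id
                label_seqs[si].labels[idx] = ("B-" if j == 0 else "I-") + cls
            break
    return label_seqs


def decode_iob2(
    tokens: TokenSequence, labels: LabelSequence, text: str | None = None
) -> list[EntityMention]:
    """Recover mentions from an IOB2-labelled sentence.

    The inverse of :func:`encode_iob2` for boundary-aligned mentions.
    An ill-formed I-X following O-Reaction (or an I/B of another class) is
    repaired by treating it as B-X, with a warning.
    """
    if len(tokens) != len(labels):
        raise ValueError(
            f"token/label length mismatch: {len(tokens)} vs {len(labels)}"
        )
    mentions: list[EntityMention] = []
    current: list[Token] | None = None
    current_cls = ""

    def flush() -> None:
        nonlocal current
        if current:
            span = Span(current[0].span.start, current[-1].span.end)
            surface = (
                text[span.start : span.end]
                if text is not None
                else " ".join(t.surface for t in current)
            )
            mentions.append(
                EntityMention(
                    mention_id=f"d{len(mentions)}",
                    span=span,
                    surface=surface,
                    entity_type=_CLASS_TO_TYPE[current_cls],
                    identifiers=[],
                )
            )
        current = None

    for tok, lab in zip(tokens.tokens, labels.labels):
        if lab == OUTSIDE:
            flush()
            continue
        prefix, cls = lab.split("-", 1)
        if prefix == "I" and (current is None or cls != current_cls):
            warnings.warn(
                f"ill-formed {lab} without preceding B-{cls}; treated as B-{cls}",
                stacklevel=2,
            )
            prefix = "B"
        if prefix == "B":
            flush()
            current, current_cls = [tok], cls
        else:
            current.append(tok)
    flush()
    return mentions


def write_conll(
    token_seqs: list[TokenSequence],
    label_seqs: list[LabelSequence],
    fh,
) -> None:
    """Write token/label pairs as two-column TSV, blank line per sentence."""
    for ts, ls in zip(token_seqs, label_seqs):
        for tok, lab in zip(ts.tokens, ls.labels):
            fh.write(f"{tok.surface}\t{lab}\n")
        fh.write("\n")
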