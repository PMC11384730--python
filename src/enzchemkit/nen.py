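"""Sieve-based chemical named-entity normalization.

Maps chemical mentions to identifiers in a target lexicon (typically ChEBI
or MeSH) through a candidate-resolution sieve: abbreviation expansion,
then five lookup steps of decreasing precision that stop at the first hit,
then document-level post-processing. Cross-lexicon steps (4 and 5) map
candidates found in other registered lexicons back to the target either
through direct ID cross-references ('single') or through shared structural
keys ('pivot'), with InChIKey preferred over SMILES over CAS — InChIKey
being the most collision-resistant of the three.

A pH-7.3 remapping table (ChEBI ID -> ChEBI ID of the major protonation
state at pH 7.3, the form used by reaction knowledgebases) supports the
downstream chemical-pair comparison.
"""

from __future__ import annotations

import logging
import os
import re
import warnings
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

PIVOT_KEYS = ("InChIKey", "SMILES", "CAS")

_NON_ALNUM = re.compile(r"[^a-z0-9]+")


def process_term(raw: str) -> str:
    """Lowercase and strip non-alphanumeric characters: e -> e_p."""
    return _NON_ALNUM.sub("", raw.lower())


def stem_term(term: str) -> str:
    """Porter-style suffix stemming of an already-processed term.

    A deliberately small rule set covering the plural and participle
    suffixes that matter for chemical/biomedical synonyms; recorded in
    configuration so results are labelled with the stemmer used.
    """
    t = term
    if t.endswith("sses"):
        t = t[:-2]
    elif t.endswith("ies"):
        t = t[:-2]
    elif t.endswith("ss"):
        pass
    elif t.endswith("s") and len(t) > 3:
        t = t[:-1]
    for suffix in ("ing", "ed"):
        if t.endswith(suffix) and len(t) - len(suffix) >= 3:
            t = t[: -len(suffix)]
            break
    return t


STEMMER_NAME = "porter-lite"


@dataclass(frozen=True)
class MentionQuery:
    """A surface string with its processed and stemmed forms."""

    raw: str
    processed: str = ""
    stemmed: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "processed", process_term(self.raw))
        object.__setattr__(self, "stemmed", stem_term(self.processed))


@dataclass(frozen=True)
class NormalizationResult:
    """Sieve outcome: candidate IDs, the step that matched, and the route.

    ``step`` is 1-5 (0 for no match); step k > 0 implies steps 1..k-1
    produced no candidates. ``via`` is 'direct' for in-lexicon steps,
    'single' for ID cross-reference mapping, or 'pivot:<key>'.
    """

    ids: tuple[str, ...]
    step: int
    via: str = "direct"


class LexiconConfigError(ValueError):
    """Raised when the sieve is asked to use an unregistered lexicon."""


class Lexicon:
    """An ID -> synonyms store with optional cross-references.

    Synonym lookup is exact-string over stored forms; processed and
    stemmed indexes are maintained alongside for the fuzzier sieve steps.
    Cross-references map an ID to values keyed by either a structural key
    (InChIKey, SMILES, CAS) or another lexicon's name (a direct 'single'
    cross-reference, e.g. a MeSH entry pointing at a ChEBI ID).
    """

    def __init__(self, name: str):
        self.name = name
        self.synonyms: dict[str, list[str]] = {}
        self.xrefs: dict[str, dict[str, str]] = {}
        self._exact: dict[str, set[str]] = {}
        self._processed: dict[str, set[str]] = {}
        self._stemmed: dict[str, set[str]] = {}
        self._by_xref: dict[tuple[str, str], set[str]] = {}

    def add(self, identifier: str, synonym: str) -> None:
        self.synonyms.setdefault(identifier, []).append(synonym)
        self._exact.setdefault(synonym, set()).add(identifier)
        p = process_term(synonym)
        if p:
            self._processed.setdefault(p, set()).add(identifier)
            self._stemmed.setdefault(stem_term(p), set()).add(identifier)

    def add_xref(self, identifier: str, key: str, value: str) -> None:
        self.xrefs.setdefault(identifier, {})[key] = value
        self._by_xref.setdefault((key, value), set()).add(identifier)

    def ids(self) -> set[str]:
        return set(self.synonyms) | set(self.xrefs)

    def find_exact(self, term: str) -> set[str]:
        return set(self._exact.get(term, ()))

    def find_processed(self, processed: str) -> set[str]:
        return set(self._processed.get(processed, ()))

    def find_stemmed(self, stemmed: str) -> set[str]:
        return set(self._stemmed.get(stemmed, ()))

    def ids_for_xref(self, key: str, value: str) -> set[str]:
        return set(self._by_xref.get((key, value), ()))

    @classmethod
    def from_tsv(cls, name: str, path: str | os.PathLike) -> "Lexicon":
        """Load ``id<TAB>synonym`` rows plus ``id<TAB>key<TAB>value`` xrefs."""
        lex = cls(name)
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) == 2:
                    lex.add(parts[0], parts[1])
                elif len(parts) == 3:
                    lex.add_xref(parts[0], parts[1], parts[2])
        return lex


def _map_to_target(
    candidates: dict[str, set[str]], target: Lexicon, all_lexicons: dict[str, Lexicon]
) -> tuple[set[str], str]:
    """Map IDs found in other lexicons onto the target lexicon.

    'single' (direct cross-reference) is preferred over 'pivot' (shared
    structural key); pivots are tried in ``PIVOT_KEYS`` precedence order.
    """
    single: set[str] = set()
    for lex_name, ids in candidates.items():
        lex = all_lexicons[lex_name]
        for i in ids:
            ref = lex.xrefs.get(i, {}).get(target.name)
            if ref:
                single.add(ref)
    if single:
        return single, "single"
    for key in PIVOT_KEYS:
        pivot: set[str] = set()
        for lex_name, ids in candidates.items():
            lex = all_lexicons[lex_name]
            for i in ids:
                value = lex.xrefs.get(i, {}).get(key)
                if value:
                    pivot |= target.ids_for_xref(key, value)
        if pivot:
            return pivot, f"pivot:{key}"
    return set(), "direct"


def lookup(
    query: MentionQuery | str,
    target: Lexicon,
    all_lexicons: dict[str, Lexicon] | list[Lexicon],
) -> NormalizationResult:
    """Run the five-step candidate lookup sieve for one mention.

    Steps, evaluated strictly in order and stopping at the first non-empty
    candidate set:

    1. the raw surface form in the target lexicon;
    2. the processed form (lowercased, non-alphanumerics stripped) in the
       target lexicon;
    3. the stemmed processed form in the target lexicon (synonyms stemmed
       on the lexicon side too);
    4. the processed form in the union of all registered lexicons, mapped
       back to the target;
    5. the stemmed form in the union of all lexicons, mapped to the target.
    """
    if isinstance(query, str):
        query = MentionQuery(query)
    if isinstance(all_lexicons, list):
        all_lexicons = {l.name: l for l in all_lexicons}
    if target.name not in all_lexicons or all_lexicons[target.name] is not target:
        raise LexiconConfigError(
            f"target lexicon {target.name!r} is not registered among "
            f"{sorted(all_lexicons)}"
        )
    others = {n: l for n, l in all_lexicons.items() if n != target.name}

    ids = target.find_exact(query.raw)
    if ids:
        return NormalizationResult(tuple(sorted(ids)), 1)
    ids = target.find_processed(query.processed)
    if ids:
        return NormalizationResult(tuple(sorted(ids)), 2)
    ids = target.find_stemmed(query.stemmed)
    if ids:
        return NormalizationResult(tuple(sorted(ids)), 3)
    found = {n: l.find_processed(query.processed) for n, l in others.items()}
    found = {n: s for n, s in found.items() if s}
    if found:
        mapped, via = _map_to_target(found, target, all_lexicons)
        if mapped:
            return NormalizationResult(tuple(sorted(mapped)), 4, via)
    found = {n: l.find_stemmed(query.stemmed) for n, l in others.items()}
    found = {n: s for n, s in found.items() if s}
    if found:
        mapped, via = _map_to_target(found, target, all_lexicons)
        if mapped:
            return NormalizationResult(tuple(sorted(mapped)), 5, via)
    return NormalizationResult((), 0)


# ---------------------------------------------------------------------------
# Abbreviation resolution (short form in parentheses, long form before it)


def _extract_long_form(short: str, before: str) -> str | None:
    """Classical right-to-left character alignment heuristic."""
    words = before.split()
    max_words = min(len(short) + 5, len(short) * 2)
    candidate_words = words[-max_words:] if words else []
    long_form = " ".join(candidate_words)
    s_i = len(short) - 1
    l_i = len(long_form) - 1
    while s_i >= 0:
        c = short[s_i].lower()
        if not c.isalnum():
            s_i -= 1
            continue
        while l_i >= 0 and (
            long_form[l_i].lower() != c or (s_i == 0 and l_i > 0 and long_form[l_i - 1].isalnum())
        ):
            l_i -= 1
        if l_i < 0:
            return None
        l_i -= 1
        s_i -= 1
    start = long_form.rfind(" ", 0, l_i + 2) + 1
    result = long_form[start:].strip() if long_form else None
    return result or long_form or None


def _plausible_short_form(s: str) -> bool:
    return (
        2 <= len(s) <= 10
        and len(s.split()) <= 2
        and any(ch.isalpha() for ch in s)
        and s[0].isalnum()
    )


_PAREN_RE = re.compile(r"\(([^()]*)\)")


def expand_abbreviations(doc_text: str) -> dict[str, str]:
    """Detect short-form -> long-form pairs defined in parentheses.

    Scans parentheticals innermost-first. A parenthetical that looks like
    an abbreviation ("triphenyl phosphate (TPP)") is aligned right-to-left
    against the preceding words; a parenthetical of more than two words is
    instead treated as the long form of the immediately preceding token
    ("D-dopachrome (2-carboxy-2,3-dihydroindole-5,6-quinone)" style).
    """
    pairs: dict[str, str] = {}
    text = doc_text
    while True:
        m = _PAREN_RE.search(text)
        if m is None:
            break
        inner = m.group(1).strip()
        before = text[: m.start()].rstrip()
        if _plausible_short_form(inner):
            long_form = _extract_long_form(inner, before)
            if long_form and long_form.lower() != inner.lower():
                pairs.setdefault(inner, long_form)
        elif len(inner.split()) > 2 or len(inner) > 10:
            prev = before.split()[-1] if before.split() else ""
            prev = prev.strip(".,;:")
            if (
                prev
                and inner
                and len(prev) < len(inner)
                and any(ch.isalpha() for ch in prev)
            ):
                pairs.setdefault(prev, inner)
        # remove the innermost parenthetical and rescan
        text = text[: m.start()] + " " * (m.end() - m.start()) + text[m.end() :]
    return pairs


def normalize_mention(
    surface: str,
    target: Lexicon,
    all_lexicons: dict[str, Lexicon] | list[Lexicon],
    abbreviations: dict[str, str] | None = None,
) -> NormalizationResult:
    """Sieve lookup with conservative abbreviation expansion.

    The short form is replaced by its long form only when the long form
    yields a hit and the short form itself does not, so true chemical
    acronyms that are lexicon synonyms are never regressed.
    """
    result = lookup(surface, target, all_lexicons)
    if result.step == 0 and abbreviations and surface in abbreviations:
        expanded = lookup(abbreviations[surface], target, all_lexicons)
        if expanded.step:
            return expanded
    return result


# ---------------------------------------------------------------------------
# Post-processing


def _numeric_part(identifier: str) -> tuple[int, str]:
    digits = re.sub(r"\D", "", identifier)
    return (int(digits) if digits else 0, identifier)


def postprocess(
    doc_results: dict[str, NormalizationResult],
    queries: dict[str, MentionQuery],
    stoplist: set[str] | frozenset[str] = frozenset(),
) -> dict[str, str]:
    """Resolve a document's sieve results to one final ID per mention.

    Mentions whose processed form is on the non-chemical stoplist are
    dropped. An ambiguous mention (two or more candidates) keeps the
    candidate that some unambiguous mention in the same document resolved
    to — preferring an unambiguous mention with the same processed form,
    else any in the document. Remaining ties break to the lowest numeric
    ID, with a warning. Keys without any candidate are omitted.
    """
    final: dict[str, str] = {}
    unambiguous_by_form: dict[str, set[str]] = {}
    unambiguous_ids: set[str] = set()
    for mid, res in doc_results.items():
        if len(res.ids) == 1:
            form = queries[mid].processed if mid in queries else ""
            unambiguous_by_form.setdefault(form, set()).add(res.ids[0])
            unambiguous_ids.add(res.ids[0])

    for mid, res in doc_results.items():
        q = queries.get(mid)
        if q is not None and q.processed in stoplist:
            continue
        if not res.ids:
            continue
        if len(res.ids) == 1:
            final[mid] = res.ids[0]
            continue
        candidates = set(res.ids)
        same_form = (
            candidates & unambiguous_by_form.get(q.processed, set()) if q else set()
        )
        evidence = same_form or (candidates & unambiguous_ids)
        pool = evidence or candidates
        chosen = min(pool, key=_numeric_part)
        if len(pool) > 1:
            warnings.warn(
                f"ambiguous mention {mid}: {sorted(pool)} -> {chosen} "
                "(lowest numeric ID tie-break)",
                stacklevel=2,
            )
        final[mid] = chosen
    return final


# ---------------------------------------------------------------------------
# pH 7.3 ChEBI remapping


class Ph73Mapping:
    """ChEBI ID -> ChEBI ID of the major protonation state at pH 7.3.

    Application is idempotent: mapping targets map to themselves.
    """

    def __init__(self, mapping: dict[str, str] | None = None):
        self.mapping = dict(mapping or {})

    def __len__(self) -> int:
        return len(self.mapping)

    def apply(self, identifier: str) -> str:
        return self.mapping.get(identifier, identifier)

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "Ph73Mapping":
        """Parse a two-ChEBI-column TSV; a header row is tolerated."""
        mapping: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                src, dst = parts[0].strip(), parts[1].strip()
                if not (src.startswith("CHEBI:") and dst.startswith("CHEBI:")):
                    continue  # header or malformed row
                mapping[src] = dst
        return cls(mapping)


def apply_ph73(identifier: str, mapping: Ph73Mapping) -> str:
    """Map a ChEBI ID to its pH-7.3 form; unknown IDs pass through."""
    return mapping.apply(identifier)
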