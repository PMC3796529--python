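"""Gazetteer (dictionary) labelers and the modifier-composition rule labeler.

Dictionary labelers perform longest-string matching of lexicon entries
against token n-grams, case-insensitively and normalising for plurals.
One lexicon per entity class (term lists typically extracted from
ontologies such as HPO/MP/PATO for phenotypes, FMA and the Brenda tissue
ontology for anatomy, Jochem for chemicals).

The rule labeler composes phenotype candidates from a modifier list
(quality/abnormality words) and head-term matches from other-class
lexicons: a head match extended over contiguous modifier tokens is
relabeled PH, reflecting the entity+quality structure of post-composed
phenotypes ("high IgE levels", "intestinal inflammation").
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from .model import O_TAG

__all__ = [
    "Lexicon",
    "ModifierList",
    "LexiconError",
    "normalize_plural",
    "normalize_term",
    "load_lexicon",
    "load_lexicon_file",
    "parse_obo_terms",
    "dict_label",
    "rule_label",
]


class LexiconError(ValueError):
    pass


def normalize_plural(token_text: str) -> str:
    """Deterministic rule-based singularization.

    Strips ``ies`` → ``y``; ``es`` after s/x/z/ch/sh; otherwise a final
    ``s`` (token longer than 3 characters, not ending in ``ss``).  This is
    a string rule, not a linguistic claim — irregular plurals pass through.
    """
    t = token_text
    if len(t) > 4 and t.endswith("ies"):
        return t[:-3] + "y"
    if len(t) > 3 and t.endswith("es") and (
        t[-3] in "sxz" or t[-4:-2] in ("ch", "sh")
    ):
        return t[:-2]
    if len(t) > 3 and t.endswith("s") and not t.endswith("ss"):
        return t[:-1]
    return t


def normalize_term(term: str) -> str:
    """Lower-case, whitespace-collapse and plural-normalize every token."""
    parts = term.lower().split()
    return " ".join(normalize_plural(p) for p in parts)


@dataclass(frozen=True)
class Lexicon:
    """A normalized term set for one entity class, from one named source."""

    entity_class: str
    entries: frozenset[str]
    source: str = "lexicon"
    max_tokens: int = field(default=1)

    @staticmethod
    def build(terms, entity_class: str, source: str = "lexicon") -> "Lexicon":
        entries = frozenset(
            normalize_term(t) for t in terms if t and t.strip()
        )
        if not entries:
            raise LexiconError(
                f"lexicon {source!r} for class {entity_class} has no entries"
            )
        return Lexicon(
            entity_class=entity_class,
            entries=entries,
            source=source,
            max_tokens=max(len(e.split()) for e in entries),
        )

    def merge(self, other: "Lexicon") -> "Lexicon":
        if other.entity_class != self.entity_class:
            raise LexiconError("cannot merge lexicons of different classes")
        return Lexicon(
            entity_class=self.entity_class,
            entries=self.entries | other.entries,
            source=f"{self.source}+{other.source}",
            max_tokens=max(self.max_tokens, other.max_tokens),
        )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class ModifierList:
    """Quality/abnormality modifier terms used by the rule labeler."""

    terms: frozenset[str]
    source: str = "modifiers"

    @staticmethod
    def build(terms, source: str = "modifiers") -> "ModifierList":
        entries = frozenset(normalize_term(t) for t in terms if t and t.strip())
        if not entries:
            raise LexiconError("modifier list has no entries")
        return ModifierList(terms=entries, source=source)

    def __contains__(self, token_norm: str) -> bool:
        return token_norm in self.terms


def load_lexicon(term_records, entity_class: str, source: str = "lexicon") -> Lexicon:
    """Build a lexicon from term records.

    Each record is either a bare term string or a TSV line
    ``term<TAB>synonym<TAB>synonym...``; terms and synonyms are flattened
    into one entry set, duplicates removed after normalization.
    """
    terms: list[str] = []
    for rec in term_records:
        for part in str(rec).split("\t"):
            part = part.strip()
            if part:
                terms.append(part)
    return Lexicon.build(terms, entity_class, source)


_OBO_SYN_TEXT_RE = re.compile(r'"((?:[^"\\]|\\.)*)"')


def parse_obo_terms(obo_content: str) -> list[str]:
    """Extract term names and synonym strings from OBO [Term] stanzas."""
    import io
    import logging

    import obonet

    logging.getLogger().disabled = True
    try:
        graph = obonet.read_obo(io.StringIO(obo_content))
    finally:
        logging.getLogger().disabled = False
    terms: list[str] = []
    for _node, data in graph.nodes(data=True):
        if "name" in data:
            terms.append(data["name"].strip())
        for syn in data.get("synonym", []):
            m = _OBO_SYN_TEXT_RE.search(syn)
            if m:
                terms.append(m.group(1).replace('\\"', '"').strip())
    return terms


def load_lexicon_file(
    path: str | Path, entity_class: str, source: str | None = None
) -> Lexicon:
    """Load a lexicon from a plain-text, TSV, or OBO file (by extension)."""
    path = Path(path)
    name = source or path.stem
    content = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".obo":
        return Lexicon.build(parse_obo_terms(content), entity_class, name)
    return load_lexicon(
        (ln for ln in content.splitlines() if ln.strip() and not ln.startswith("#")),
        entity_class,
        name,
    )


def _match_spans(
    norm_tokens: list[str], lexicon: Lexicon
) -> list[tuple[int, int]]:
    """Leftmost-longest non-overlapping matches as token-index spans."""
    spans = []
    i = 0
    n = len(norm_tokens)
    while i < n:
        hit = None
        for length in range(min(lexicon.max_tokens, n - i), 0, -1):
            if " ".join(norm_tokens[i : i + length]) in lexicon.entries:
                hit = length
                break
        if hit is None:
            i += 1
        else:
            spans.append((i, i + hit))
            i += hit
    return spans


def dict_label(sentence_tokens: list[str], lexicon: Lexicon) -> list[str]:
    """Longest-string dictionary matching, emitted as BIO tags.

    Scans left to right; at each position the longest token n-gram whose
    normalized join is a lexicon entry wins and scanning resumes after it.
    """
    norm = [normalize_plural(t.lower()) for t in sentence_tokens]
    tags = [O_TAG] * len(sentence_tokens)
    for s, e in _match_spans(norm, lexicon):
        tags[s] = f"B-{lexicon.entity_class}"
        for j in range(s + 1, e):
            tags[j] = f"I-{lexicon.entity_class}"
    return tags


def rule_label(
    sentence_tokens: list[str],
    modifier_list: ModifierList,
    head_lexicons: dict[str, Lexicon],
    emit_heads: bool = False,
) -> list[str]:
    """Modifier-composition rule labeler.

    Stages: (1) match head terms from the supplied lexicons (typically AN,
    GG, DS); (2) extend each head match over contiguous modifier tokens on
    both sides; (3) any span extended beyond the bare head is relabeled
    PH.  Unextended heads are emitted with their own class only when
    ``emit_heads`` is set; the default emits phenotype compositions only.
    """
    norm = [normalize_plural(t.lower()) for t in sentence_tokens]
    n = len(norm)
    candidates: list[tuple[int, int, str]] = []
    for cls in sorted(head_lexicons):
        lex = head_lexicons[cls]
        for s, e in _match_spans(norm, lex):
            ls = s
            while ls > 0 and norm[ls - 1] in modifier_list:
                ls -= 1
            le = e
            while le < n and norm[le] in modifier_list:
                le += 1
            if ls < s or le > e:
                candidates.append((ls, le, "PH"))
            elif emit_heads:
                candidates.append((s, e, cls))
    # leftmost-longest non-overlapping selection over the candidates
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), c[2]))
    tags = [O_TAG] * n
    occupied_until = 0
    for s, e, cls in candidates:
        if s < occupied_until:
            continue
        tags[s] = f"B-{cls}"
        for j in range(s + 1, e):
            tags[j] = f"I-{cls}"
        occupied_until = e
    return tags
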