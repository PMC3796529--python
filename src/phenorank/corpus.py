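"""BRAT standoff corpus I/O, sentence segmentation, tokenization, and
abbreviation expansion.

A corpus is a directory of paired ``<id>.txt`` / ``<id>.ann`` files (BRAT
standoff, UTF-8, character offsets 0-based half-open).  Only the entity
layer (``T`` lines) is read; relation/event/note lines are ignored.

The tokenizer is deliberately rule-based and deterministic: whitespace
splitting with punctuation detached, keeping hyphenated and
apostrophe-joined biomedical tokens ("non-obese", "Crohn's") intact.
Sentence boundaries are placed after ``.!?`` runs followed by whitespace
and an upper-case letter, digit, or opening bracket/quote — a heuristic
that intentionally refuses to split after "E. coli"-style abbreviations
followed by lower case.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

from .model import DEFAULT_CLASSES, Document, Mention

__all__ = [
    "BratParseError",
    "BratValidationError",
    "AbbreviationPair",
    "segment_and_tokenize",
    "read_brat",
    "write_brat",
    "read_brat_dir",
    "write_brat_dir",
    "find_abbreviations",
    "expand_abbreviations",
    "to_conll",
]


class BratParseError(ValueError):
    pass


class BratValidationError(ValueError):
    pass


_TOKEN_RE = re.compile(r"\w+(?:['-]\w+)*|[^\w\s]")
_SENT_BREAK_RE = re.compile(r"[.!?]+(\s+)(?=[A-Z0-9(\[\"'])")


def segment_and_tokenize(
    text: str,
) -> tuple[list[tuple[int, int]], list[list[tuple[int, int]]]]:
    """Split text into sentence spans and per-sentence token spans.

    Offsets index into ``text`` directly, so the original text is fully
    reconstructable; spans never cover whitespace.
    """
    sentences: list[tuple[int, int]] = []
    start = 0
    for m in _SENT_BREAK_RE.finditer(text):
        end = m.start(1)
        if text[start:end].strip():
            sentences.append((start, end))
        start = m.end(1)
    if text[start:].strip():
        sentences.append((start, len(text)))
    # trim whitespace off sentence edges
    trimmed = []
    for s, e in sentences:
        while s < e and text[s].isspace():
            s += 1
        while e > s and text[e - 1].isspace():
            e -= 1
        if s < e:
            trimmed.append((s, e))
    tokens = [
        [(s + m.start(), s + m.end()) for m in _TOKEN_RE.finditer(text[s:e])]
        for s, e in trimmed
    ]
    return trimmed, tokens


_ENTITY_LINE_RE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")


def read_brat(
    text_content: str,
    ann_content: str,
    doc_id: str = "doc",
    classes: tuple[str, ...] = DEFAULT_CLASSES,
) -> Document:
    """Parse a BRAT .txt/.ann pair into a :class:`Document`.

    Entity lines have the form ``Tid<TAB>Class start end<TAB>surface``.
    A surface string that does not equal the text slice raises
    :class:`BratValidationError` naming the offending annotation ids.
    Classes outside ``classes`` are kept but reported with a warning.
    """
    mentions: list[Mention] = []
    bad: list[str] = []
    unknown: list[str] = []
    for ln, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip() or not line.startswith("T"):
            continue  # relations, events, notes, comments
        m = _ENTITY_LINE_RE.match(line)
        if m is None:
            if ";" in line.split("\t")[1] if "\t" in line else False:
                raise BratParseError(
                    f"{doc_id}.ann line {ln}: discontinuous spans unsupported"
                )
            raise BratParseError(f"{doc_id}.ann line {ln}: malformed entity line")
        tid, cls, start, end, surface = m.groups()
        start, end = int(start), int(end)
        if not (0 <= start < end <= len(text_content)):
            raise BratParseError(
                f"{doc_id}.ann line {ln}: span ({start},{end}) out of text"
            )
        if text_content[start:end] != surface:
            bad.append(
                f"{tid} [{start},{end}) text={text_content[start:end]!r} "
                f"ann={surface!r}"
            )
            continue
        if cls not in classes:
            unknown.append(f"{tid}:{cls}")
        mentions.append(Mention(start, end, cls, surface))
    if bad:
        raise BratValidationError(
            f"{doc_id}: surface mismatch for {len(bad)} annotation(s): "
            + "; ".join(bad)
        )
    if unknown:
        warnings.warn(
            f"{doc_id}: annotation classes outside inventory kept: "
            + ", ".join(unknown),
            stacklevel=2,
        )
    sents, toks = segment_and_tokenize(text_content)
    doc = Document(
        id=doc_id,
        text=text_content,
        sentences=sents,
        tokens=toks,
        gold_mentions=sorted(mentions),
    )
    doc.validate()
    return doc


def write_brat(document: Document) -> str:
    """Serialize a document's mentions as BRAT .ann content (sequential ids)."""
    lines = []
    for i, m in enumerate(sorted(document.gold_mentions), start=1):
        surface = document.text[m.start : m.end]
        lines.append(f"T{i}\t{m.entity_class} {m.start} {m.end}\t{surface}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_brat_dir(
    path: str | Path, classes: tuple[str, ...] = DEFAULT_CLASSES
) -> list[Document]:
    """Read every ``.txt``/``.ann`` pair under a directory (sorted by id)."""
    path = Path(path)
    docs = []
    for txt in sorted(path.glob("*.txt")):
        ann = txt.with_suffix(".ann")
        ann_content = ann.read_text(encoding="utf-8") if ann.exists() else ""
        docs.append(
            read_brat(
                txt.read_text(encoding="utf-8"), ann_content, txt.stem, classes
            )
        )
    if not docs:
        raise FileNotFoundError(f"no .txt files under {path}")
    return docs


def write_brat_dir(documents: list[Document], path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for d in documents:
        (path / f"{d.id}.txt").write_text(d.text, encoding="utf-8")
        (path / f"{d.id}.ann").write_text(write_brat(d), encoding="utf-8")


# ---------------------------------------------------------------------------
# Abbreviation handling (Schwartz–Hearst-style character alignment)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AbbreviationPair:
    """A (short form, long form) definition such as "non-obese diabetic (NOD)"."""

    short: str
    long: str
    short_start: int  # offset of the short form inside its parentheses
    short_end: int
    long_start: int
    long_end: int


def _valid_short_form(sf: str) -> bool:
    if not (2 <= len(sf) <= 10) or len(sf.split()) > 2:
        return False
    if not any(c.isalpha() for c in sf):
        return False
    return sf[0].isalnum()


def _find_long_form(sf: str, candidate: str) -> int | None:
    """Return the start index of the long form inside ``candidate`` or None.

    Matches the short form's characters right-to-left against the candidate
    text; the first character must match at the start of a word.
    """
    i = len(sf) - 1
    j = len(candidate) - 1
    while i >= 0:
        c = sf[i].lower()
        if not c.isalnum():
            i -= 1
            continue
        while j >= 0 and (
            candidate[j].lower() != c
            or (i == 0 and j > 0 and candidate[j - 1].isalnum())
        ):
            j -= 1
        if j < 0:
            return None
        i -= 1
        j -= 1
    return j + 1


def find_abbreviations(text: str) -> list[AbbreviationPair]:
    """Detect parenthesis-adjacent (long form, short form) definition pairs."""
    pairs = []
    for m in re.finditer(r"\(([^()]{1,60})\)", text):
        sf = m.group(1).strip()
        if not _valid_short_form(sf):
            continue
        before = text[: m.start()].rstrip()
        # candidate window: at most min(|sf|+5, 2|sf|) preceding words
        words = before.split()
        if not words:
            continue
        n_words = min(len(sf) + 5, 2 * len(sf), len(words))
        cand = " ".join(words[-n_words:])
        cand_start = len(before) - len(cand)
        rel = _find_long_form(sf, cand)
        if rel is None:
            continue
        long = cand[rel:]
        if not long or len(long.split()) < 2 and long.lower() == sf.lower():
            continue
        if long.lower() == sf.lower():
            continue
        pairs.append(
            AbbreviationPair(
                short=sf,
                long=long,
                short_start=m.start(1),
                short_end=m.end(1),
                long_start=cand_start + rel,
                long_end=cand_start + rel + len(long),
            )
        )
    return pairs


def expand_abbreviations(document: Document) -> Document:
    """Replace later standalone short-form occurrences by their long forms.

    Gold mention offsets are remapped across the rewritten text.  A
    replacement that would split a mention boundary is skipped with a
    document-level warning.  Aux streams are discarded (token positions
    change); expansion is meant to run before feature streams are built.
    """
    pairs = find_abbreviations(document.text)
    if not pairs:
        return document
    text = document.text
    # collect (start, end, replacement) edits for standalone re-occurrences
    edits: list[tuple[int, int, str]] = []
    for p in pairs:
        for m in re.finditer(re.escape(p.short), text):
            if m.start() < p.short_end:  # definition site or before it
                continue
            before_ok = m.start() == 0 or not text[m.start() - 1].isalnum()
            after_ok = m.end() == len(text) or not text[m.end()].isalnum()
            if not (before_ok and after_ok):
                continue
            edits.append((m.start(), m.end(), p.long))
    edits.sort()
    skipped = []
    new_text_parts: list[str] = []
    pos = 0
    offset_map: list[tuple[int, int, int]] = []  # (old_start, old_end, delta)
    delta = 0
    applied: list[tuple[int, int, int]] = []  # old span + delta after edit
    for s, e, repl in edits:
        if s < pos:
            continue  # overlapping edit
        # a mention boundary strictly inside [s, e) cannot be remapped
        bad = any(
            (s < m.start < e) or (s < m.end < e)
            for m in document.gold_mentions
        )
        if bad:
            skipped.append((s, e))
            continue
        new_text_parts.append(text[pos:s])
        new_text_parts.append(repl)
        applied.append((s, e, delta))
        delta += len(repl) - (e - s)
        pos = e
    new_text_parts.append(text[pos:])
    if skipped:
        warnings.warn(
            f"{document.id}: skipped {len(skipped)} abbreviation replacement(s) "
            "that would split a mention",
            stacklevel=2,
        )
    if not applied:
        return document
    new_text = "".join(new_text_parts)

    def remap_offset(offset: int) -> int:
        d = 0
        for s, e, _ in applied:
            if e <= offset:
                d += len(_repl_for(edits, s, e)) - (e - s)
        return offset + d

    mapped_mentions = []
    for m in document.gold_mentions:
        ns, ne = remap_offset(m.start), remap_offset(m.end)
        mapped_mentions.append(Mention(ns, ne, m.entity_class, new_text[ns:ne]))
    sents, toks = segment_and_tokenize(new_text)
    doc = Document(
        id=document.id,
        text=new_text,
        sentences=sents,
        tokens=toks,
        gold_mentions=mapped_mentions,
    )
    doc.validate()
    return doc


def _repl_for(edits: list[tuple[int, int, str]], s: int, e: int) -> str:
    for es, ee, repl in edits:
        if es == s and ee == e:
            return repl
    raise KeyError((s, e))


def to_conll(document: Document, streams: tuple[str, ...] = ()) -> str:
    """CoNLL-style TSV export: token, aux streams, gold BIO; blank line
    between sentences."""
    lines = []
    for i in range(document.n_sentences):
        tags = document.gold_bio(i).tags
        toks = document.token_texts(i)
        for j, tok in enumerate(toks):
            cols = [tok]
            for s in streams:
                cols.append(document.aux_streams[s][i][j])
            cols.append(tags[j])
            lines.append("\t".join(cols))
        lines.append("")
    return "\n".join(lines)
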