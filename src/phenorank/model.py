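"""Core domain types for span-based named entity recognition with BIO tagging.

The package recognises six entity classes in biomedical abstracts:

====  =========================================================
code  meaning
====  =========================================================
PH    phenotype candidate (entity + quality, e.g. "high IgE levels")
GG    gene or gene product
DS    disease
OR    organism (species or individuals)
AN    anatomical entity
CD    chemical or drug
====  =========================================================

Mentions are character spans (0-based, half-open, BRAT convention) over the
document text.  Per sentence, mentions are encoded with the BIO scheme:
``B-X`` begins an entity of class X, ``I-X`` continues it, ``O`` is outside
any entity.  Gene mentions may nest inside phenotype mentions ("high
[IgE]_GG levels" as a PH); BIO cannot express nesting, so the outermost
mention wins when encoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "DEFAULT_CLASSES",
    "O_TAG",
    "Mention",
    "Document",
    "LabelSequence",
    "CandidateSet",
    "tag_class",
    "bio_labels",
    "repair_bio",
    "is_wellformed",
    "mentions_to_bio",
    "bio_to_mentions",
    "tags_to_token_spans",
    "token_spans_to_tags",
]

#: Entity class inventory.  Closed by default but every operation accepts an
#: explicit inventory, so configurations may extend it.
DEFAULT_CLASSES: tuple[str, ...] = ("PH", "GG", "DS", "OR", "AN", "CD")

#: The reserved non-entity label.  Never a member of the class inventory.
O_TAG = "O"


class BoundaryError(ValueError):
    """A mention crosses a sentence boundary or overlaps illegally."""


def tag_class(tag: str) -> str | None:
    """Entity class of a BIO tag, or None for ``O``."""
    if tag == O_TAG:
        return None
    return tag[2:]


def bio_labels(classes: tuple[str, ...] = DEFAULT_CLASSES) -> tuple[str, ...]:
    """The full BIO label inventory (sorted, stable) for a class set."""
    labels = [O_TAG]
    for c in classes:
        labels.append(f"B-{c}")
        labels.append(f"I-{c}")
    return tuple(sorted(labels))


@dataclass(frozen=True, order=True)
class Mention:
    """An entity mention: class plus character span plus surface string."""

    start: int
    end: int
    entity_class: str
    surface: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"mention span must be non-empty: [{self.start},{self.end})"
            )

    def overlaps(self, other: "Mention") -> bool:
        return self.start < other.end and other.start < self.end

    def contains(self, other: "Mention") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class Document:
    """A text with sentence/token segmentation and gold mentions.

    ``sentences`` are character spans over ``text``; ``tokens`` holds, per
    sentence, the token character spans (nested within their sentence).
    ``aux_streams`` carries named per-token tag columns (part of speech,
    species tags, external tagger output) aligned with ``tokens``.
    """

    id: str
    text: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tokens: list[list[tuple[int, int]]] = field(default_factory=list)
    gold_mentions: list[Mention] = field(default_factory=list)
    aux_streams: dict[str, list[list[str]]] = field(default_factory=dict)

    def validate(self) -> None:
        prev_end = 0
        if len(self.sentences) != len(self.tokens):
            raise ValueError(f"{self.id}: sentences/tokens length mismatch")
        for (s, e), toks in zip(self.sentences, self.tokens):
            if not (0 <= s < e <= len(self.text)):
                raise ValueError(f"{self.id}: sentence span ({s},{e}) out of text")
            if s < prev_end:
                raise ValueError(f"{self.id}: overlapping sentence spans")
            prev_end = e
            t_prev = s
            for ts, te in toks:
                if not (s <= ts < te <= e):
                    raise ValueError(
                        f"{self.id}: token ({ts},{te}) outside sentence ({s},{e})"
                    )
                if ts < t_prev:
                    raise ValueError(f"{self.id}: overlapping token spans")
                t_prev = te
        for m in self.gold_mentions:
            if m.surface and self.text[m.start : m.end] != m.surface:
                raise ValueError(
                    f"{self.id}: mention surface {m.surface!r} != text slice "
                    f"{self.text[m.start:m.end]!r} at [{m.start},{m.end})"
                )
        for name, stream in self.aux_streams.items():
            if len(stream) != len(self.tokens) or any(
                len(col) != len(toks) for col, toks in zip(stream, self.tokens)
            ):
                raise ValueError(f"{self.id}: aux stream {name!r} misaligned")

    @property
    def n_sentences(self) -> int:
        return len(self.sentences)

    def sentence_text(self, i: int) -> str:
        s, e = self.sentences[i]
        return self.text[s:e]

    def token_texts(self, i: int) -> list[str]:
        return [self.text[s:e] for s, e in self.tokens[i]]

    def sentence_mentions(self, i: int, mentions: list[Mention] | None = None) -> list[Mention]:
        """Mentions falling inside sentence ``i``; raises on boundary crossers."""
        src = self.gold_mentions if mentions is None else mentions
        s, e = self.sentences[i]
        out = []
        for m in src:
            if m.end <= s or m.start >= e:
                continue
            if not (s <= m.start and m.end <= e):
                raise BoundaryError(
                    f"{self.id}: mention {m} crosses boundary of sentence {i}"
                )
            out.append(m)
        return out

    def gold_bio(self, i: int) -> "LabelSequence":
        """Gold BIO tags for sentence ``i`` (outermost mentions win)."""
        return LabelSequence(
            source="gold",
            tags=tuple(mentions_to_bio(self.tokens[i], self.sentence_mentions(i))),
        )


@dataclass(frozen=True)
class LabelSequence:
    """One labeler's BIO hypothesis for a single sentence."""

    source: str
    tags: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tags)

    def repaired(self) -> "LabelSequence":
        return replace(self, tags=tuple(repair_bio(self.tags)))


@dataclass
class CandidateSet:
    """Competing labeler hypotheses for one sentence, input to resolution."""

    sentence_index: int
    hypotheses: dict[str, LabelSequence]

    def __post_init__(self) -> None:
        lengths = {len(h) for h in self.hypotheses.values()}
        if len(lengths) > 1:
            raise ValueError(f"hypothesis length mismatch: {lengths}")
        for src, h in self.hypotheses.items():
            if h.source != src:
                raise ValueError(f"hypothesis keyed {src!r} has source {h.source!r}")

    @property
    def n_tokens(self) -> int:
        return len(next(iter(self.hypotheses.values()))) if self.hypotheses else 0

    @property
    def sources(self) -> list[str]:
        return list(self.hypotheses)


def is_wellformed(tags: tuple[str, ...] | list[str]) -> bool:
    """True if no I-X follows O, start, or a tag of a different class."""
    prev: str | None = None
    for t in tags:
        if t.startswith("I-"):
            if prev is None or prev == O_TAG or tag_class(prev) != tag_class(t):
                return False
        prev = t
    return True


def repair_bio(tags: tuple[str, ...] | list[str]) -> list[str]:
    """Rewrite dangling I-X to B-X (recall-preserving CoNLL-style repair)."""
    out: list[str] = []
    prev: str | None = None
    for t in tags:
        if t.startswith("I-") and (
            prev is None or prev == O_TAG or tag_class(prev) != tag_class(t)
        ):
            t = "B-" + t[2:]
        out.append(t)
        prev = t
    return out


def mentions_to_bio(
    token_spans: list[tuple[int, int]], mentions: list[Mention]
) -> list[str]:
    """Encode mentions as per-token BIO tags over one sentence.

    Nested mentions are flattened to the outermost (BIO cannot express
    nesting).  Overlapping mentions that are not strictly nested are
    rejected, as are same-class duplicates over the same span.
    """
    if token_spans:
        s_lo, s_hi = token_spans[0][0], token_spans[-1][1]
        for m in mentions:
            if m.start >= s_hi or m.end <= s_lo:
                raise BoundaryError(f"mention {m} outside sentence token range")
    # keep outermost only
    outer: list[Mention] = []
    for m in mentions:
        if any(o is not m and o.contains(m) and not m.contains(o) for o in mentions):
            continue
        outer.append(m)
    outer.sort()
    for a, b in zip(outer, outer[1:]):
        if a.overlaps(b):
            raise BoundaryError(f"overlapping non-nested mentions: {a} / {b}")
    tags = [O_TAG] * len(token_spans)
    for m in outer:
        first = True
        for i, (ts, te) in enumerate(token_spans):
            if ts < m.end and m.start < te:  # token overlaps mention
                tags[i] = ("B-" if first else "I-") + m.entity_class
                first = False
    return tags


def bio_to_mentions(
    tags: list[str] | tuple[str, ...],
    token_spans: list[tuple[int, int]],
    text: str | None = None,
) -> list[Mention]:
    """Decode (repaired) BIO tags into mentions with character spans."""
    tags = repair_bio(tags)
    out: list[Mention] = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B-"):
            cls = tag_class(tags[i])
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{cls}":
                j += 1
            start = token_spans[i][0]
            end = token_spans[j - 1][1]
            surface = text[start:end] if text is not None else ""
            out.append(Mention(start, end, cls, surface))
            i = j
        else:
            i += 1
    return out


def tags_to_token_spans(
    tags: list[str] | tuple[str, ...],
) -> list[tuple[int, int, str]]:
    """Token-index spans (start, end, class) from repaired BIO tags."""
    tags = repair_bio(tags)
    spans = []
    i = 0
    while i < len(tags):
        if tags[i].startswith("B-"):
            cls = tags[i][2:]
            j = i + 1
            while j < len(tags) and tags[j] == f"I-{cls}":
                j += 1
            spans.append((i, j, cls))
            i = j
        else:
            i += 1
    return spans


def token_spans_to_tags(
    spans: list[tuple[int, int, str]], n_tokens: int
) -> list[str]:
    """Inverse of :func:`tags_to_token_spans` for non-overlapping spans."""
    tags = [O_TAG] * n_tokens
    for s, e, cls in sorted(spans):
        tags[s] = f"B-{cls}"
        for i in range(s + 1, e):
            tags[i] = f"I-{cls}"
    return tags
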