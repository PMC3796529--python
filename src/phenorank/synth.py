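"""Synthetic annotated corpora with controllable labeler disagreement.

The generator emulates the structural properties of a multi-class
annotated abstract collection in the auto-immune phenotype domain:
six entity classes with per-class mention densities and length
distributions (phenotype mentions average ~3 tokens, the other classes
1–2), gene mentions optionally nested inside phenotype mentions, and
per-class vocabularies with configurable dictionary coverage so the
dictionary labelers have realistic recall gaps.

Sentences are template token streams, not natural language: mentions are
drawn from class vocabularies (tokens carry a class prefix, e.g. ``ph12``)
and separated by filler tokens.  This keeps every expected output
enumerable while exercising the real BRAT readers, tokenizer, labelers
and resolvers end to end.

Default densities and vocabulary sizes are calibrated to the corpus the
task is modelled on: 122 abstracts with entity totals PH 472, OR 764,
DS 875, GG 1611, AN 188, CD 48 and unique-entity counts 393/402/270/
885/132/31, at the average lengths 3.0/1.8/1.9/1.7/2.2/1.4 tokens.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import segment_and_tokenize
from .lexicon import Lexicon
from .model import CandidateSet, Document, LabelSequence, Mention

__all__ = ["CorpusSpec", "LabelerNoise", "NoiseSpec", "SynthCorpus",
           "gen_corpus", "gen_labeler_outputs"]

_T3_TOTALS = {"PH": 472, "OR": 764, "DS": 875, "GG": 1611, "AN": 188, "CD": 48}
_T3_UNIQUE = {"PH": 393, "OR": 402, "DS": 270, "GG": 885, "AN": 132, "CD": 31}
_T3_MEANLEN = {"PH": 3.0, "OR": 1.8, "DS": 1.9, "GG": 1.7, "AN": 2.2, "CD": 1.4}
_REF_DOCS = 122
_REF_SENTS = 8


def _default_rates(n_docs: int, sentences_per_doc: int) -> dict[str, float]:
    # keep the reference per-sentence densities regardless of corpus size
    return {
        cls: total / (_REF_DOCS * _REF_SENTS) for cls, total in _T3_TOTALS.items()
    }


@dataclass
class CorpusSpec:
    """Parameters of a synthetic corpus; the seed is mandatory."""

    seed: int
    n_docs: int = _REF_DOCS
    sentences_per_doc: int = _REF_SENTS
    mention_rate: dict[str, float] = field(default_factory=dict)
    mention_length_mean: dict[str, float] = field(
        default_factory=lambda: dict(_T3_MEANLEN)
    )
    vocab_size: dict[str, int] = field(default_factory=lambda: dict(_T3_UNIQUE))
    nesting_prob: float = 0.1  # P(GG nested inside a PH mention of length >= 3)
    lexicon_coverage: float = 1.0
    filler_vocab: int = 200
    max_sentence_tokens: int = 80
    #: With a shared pool, mention tokens carry no class-specific
    #: orthography (all look like "x123"), so class identity must come from
    #: term identity (dictionaries) and context rather than word shape —
    #: the harder, more realistic setting.  Class-prefixed tokens ("ph12")
    #: make every class learnable from shape alone.
    shared_token_pool: bool = False

    def __post_init__(self) -> None:
        if not self.mention_rate:
            self.mention_rate = _default_rates(self.n_docs, self.sentences_per_doc)
        if any(r < 0 for r in self.mention_rate.values()):
            raise ValueError("mention densities must be >= 0")
        demand = sum(
            r * (self.mention_length_mean.get(c, 2.0) + 1.5)
            for c, r in self.mention_rate.items()
        )
        if demand > self.max_sentence_tokens:
            raise ValueError(
                f"densities exceed sentence capacity: expected token demand "
                f"{demand:.1f} > {self.max_sentence_tokens}"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(sorted(self.mention_rate))


@dataclass
class SynthCorpus:
    documents: list[Document]
    lexicons: dict[str, Lexicon]  # entity class -> lexicon
    vocab: dict[str, list[tuple[str, ...]]]
    spec: CorpusSpec


def _sample_length(rng: np.random.Generator, mean: float) -> int:
    return 1 + int(rng.poisson(max(mean - 1.0, 0.0)))


def _build_vocab(
    rng: np.random.Generator, spec: CorpusSpec
) -> dict[str, list[tuple[str, ...]]]:
    vocab: dict[str, list[tuple[str, ...]]] = {}
    shared_pool = None
    if spec.shared_token_pool:
        total = sum(spec.vocab_size.get(c, 50) for c in spec.classes)
        shared_pool = [f"x{k}" for k in range(max(total, 20))]
    for cls in spec.classes:
        size = spec.vocab_size.get(cls, 50)
        pool = shared_pool or [f"{cls.lower()}{k}" for k in range(max(size, 10))]
        mean = spec.mention_length_mean.get(cls, 2.0)
        terms: set[tuple[str, ...]] = set()
        attempts = 0
        while len(terms) < size and attempts < size * 50:
            L = _sample_length(rng, mean)
            term = tuple(pool[i] for i in rng.integers(0, len(pool), L))
            terms.add(term)
            attempts += 1
        vocab[cls] = sorted(terms)
    return vocab


def gen_corpus(spec: CorpusSpec) -> SynthCorpus:
    """Generate documents plus per-class lexicons, reproducibly by seed.

    Lexicons contain ``lexicon_coverage`` of the gold vocabulary
    (including nesting-induced phenotype variants), creating dictionary
    recall gaps when coverage < 1.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = _build_vocab(rng, spec)
    used_terms: dict[str, set[tuple[str, ...]]] = {c: set() for c in spec.classes}
    documents: list[Document] = []
    for d in range(spec.n_docs):
        parts: list[str] = []
        mentions: list[Mention] = []
        pos = 0
        for s in range(spec.sentences_per_doc):
            tokens: list[tuple[str, str | None]] = []  # (token, class-or-None)
            pending: list[tuple[int, int, str]] = []  # (tok_start, tok_end, cls)
            nested_pending: list[tuple[int, str]] = []  # (tok_index, cls)
            first = f"W{int(rng.integers(0, spec.filler_vocab))}"
            tokens.append((first, None))
            for cls in spec.classes:
                count = int(rng.poisson(spec.mention_rate[cls]))
                for _ in range(count):
                    terms = vocab[cls]
                    term = list(terms[int(rng.integers(0, len(terms)))])
                    nested_at: int | None = None
                    if (
                        cls == "PH"
                        and len(term) >= 3
                        and "GG" in vocab
                        and rng.random() < spec.nesting_prob
                    ):
                        gg_pool = [t for t in vocab["GG"] if len(t) == 1]
                        if gg_pool:
                            gi = int(rng.integers(0, len(gg_pool)))
                            mid = 1 + int(rng.integers(0, len(term) - 2))
                            term[mid] = gg_pool[gi][0]
                            nested_at = mid
                    start_tok = len(tokens)
                    for t in term:
                        tokens.append((t, cls))
                    pending.append((start_tok, len(tokens), cls))
                    used_terms[cls].add(tuple(term))
                    if nested_at is not None:
                        nested_pending.append((start_tok + nested_at, "GG"))
                        used_terms["GG"].add((term[nested_at],))
                    n_fill = 1 + int(rng.integers(0, 2))
                    for _ in range(n_fill):
                        tokens.append(
                            (f"w{int(rng.integers(0, spec.filler_vocab))}", None)
                        )
            tokens.append((".", None))
            # shuffle mention order? keep generation order; emit text + offsets
            tok_offsets: list[tuple[int, int]] = []
            for t, _cls in tokens:
                if parts:
                    parts.append(" ")
                    pos += 1
                tok_offsets.append((pos, pos + len(t)))
                parts.append(t)
                pos += len(t)
            for ts, te, cls in pending:
                cs_, ce_ = tok_offsets[ts][0], tok_offsets[te - 1][1]
                mentions.append(Mention(cs_, ce_, cls))
            for ti, cls in nested_pending:
                cs_, ce_ = tok_offsets[ti]
                mentions.append(Mention(cs_, ce_, cls))
        text = "".join(parts)
        sents, toks = segment_and_tokenize(text)
        mentions = [
            Mention(m.start, m.end, m.entity_class, text[m.start : m.end])
            for m in sorted(mentions)
        ]
        doc = Document(
            id=f"synth{d:04d}",
            text=text,
            sentences=sents,
            tokens=toks,
            gold_mentions=mentions,
        )
        # deterministic pseudo part-of-speech stream
        doc.aux_streams["pos"] = [
            [_pseudo_pos(t) for t in doc.token_texts(i)]
            for i in range(doc.n_sentences)
        ]
        doc.validate()
        documents.append(doc)
    lexicons: dict[str, Lexicon] = {}
    for cls in spec.classes:
        terms = sorted(set(vocab[cls]) | used_terms[cls])
        if spec.lexicon_coverage < 1.0:
            keep = rng.random(len(terms)) < spec.lexicon_coverage
            terms = [t for t, k in zip(terms, keep) if k] or terms[:1]
        lexicons[cls] = Lexicon.build(
            [" ".join(t) for t in terms], cls, source=f"LEX-{cls}"
        )
    return SynthCorpus(documents=documents, lexicons=lexicons, vocab=vocab, spec=spec)


def _pseudo_pos(token: str) -> str:
    if token == ".":
        return "PUNCT"
    return ("NN", "JJ", "DT")[sum(map(ord, token)) % 3]


# ---------------------------------------------------------------------------
# Controlled-noise labeler outputs
# ---------------------------------------------------------------------------


@dataclass
class LabelerNoise:
    """Noise profile for one simulated labeler.

    ``confusion`` maps a true class to a distribution over replacement
    classes (row sums <= 1; remaining mass keeps the true class).
    ``classes`` restricts which gold classes the labeler can see at all
    (a per-class dictionary labeler sees only its own class).
    """

    drop_rate: float = 0.0
    jitter_rate: float = 0.0
    confusion: dict[str, dict[str, float]] = field(default_factory=dict)
    classes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for r in (self.drop_rate, self.jitter_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0,1]")
        for cls, row in self.confusion.items():
            if sum(row.values()) > 1.0 + 1e-9:
                raise ValueError(f"confusion row for {cls} sums > 1")


@dataclass
class NoiseSpec:
    seed: int
    labelers: dict[str, LabelerNoise] = field(default_factory=dict)


def gen_labeler_outputs(
    documents: list[Document], noise_spec: NoiseSpec
) -> dict[str, list[CandidateSet]]:
    """Per-labeler corruption of the gold mentions, re-encoded as BIO.

    For each labeler the gold mentions are filtered to its visible
    classes, dropped at ``drop_rate``, boundary-jittered at
    ``jitter_rate`` (one boundary moves by one token) and class-confused
    per the confusion matrix; conflicting spans after jitter keep the
    earlier mention.  Fully reproducible from the spec seed.
    """
    rng = np.random.default_rng(noise_spec.seed)
    out: dict[str, list[CandidateSet]] = {}
    results: dict[str, dict[int, dict[str, LabelSequence]]] = {
        doc.id: {i: {} for i in range(doc.n_sentences)} for doc in documents
    }
    for doc in documents:
        for i in range(doc.n_sentences):
            sent_mentions = doc.sentence_mentions(i)
            token_spans = doc.tokens[i]
            n = len(token_spans)
            for name in sorted(noise_spec.labelers):
                prof = noise_spec.labelers[name]
                visible = [
                    m
                    for m in sent_mentions
                    if prof.classes is None or m.entity_class in prof.classes
                ]
                # outermost-only among the visible mentions
                visible = [
                    m
                    for m in visible
                    if not any(
                        o is not m and o.contains(m) and not m.contains(o)
                        for o in visible
                    )
                ]
                spans: list[tuple[int, int, str]] = []
                for m in visible:
                    idx = [
                        j
                        for j, (ts, te) in enumerate(token_spans)
                        if ts < m.end and m.start < te
                    ]
                    if not idx:
                        continue
                    s, e = idx[0], idx[-1] + 1
                    cls = m.entity_class
                    if rng.random() < prof.drop_rate:
                        continue
                    if rng.random() < prof.jitter_rate:
                        move = int(rng.integers(0, 4))
                        if move == 0 and s > 0:
                            s -= 1
                        elif move == 1 and e - s > 1:
                            s += 1
                        elif move == 2 and e < n:
                            e += 1
                        elif move == 3 and e - s > 1:
                            e -= 1
                    row = prof.confusion.get(cls, {})
                    if row:
                        u = rng.random()
                        acc = 0.0
                        for new_cls, prob in sorted(row.items()):
                            acc += prob
                            if u < acc:
                                cls = new_cls
                                break
                    if any(s < oe and os_ < e for os_, oe, _ in spans):
                        continue  # jitter collision: keep earlier mention
                    spans.append((s, e, cls))
                tags = ["O"] * n
                for s, e, cls in sorted(spans):
                    tags[s] = f"B-{cls}"
                    for j in range(s + 1, e):
                        tags[j] = f"I-{cls}"
                results[doc.id][i][name] = LabelSequence(name, tuple(tags))
    for doc in documents:
        out[doc.id] = [
            CandidateSet(sentence_index=i, hypotheses=results[doc.id][i])
            for i in range(doc.n_sentences)
        ]
    return out
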