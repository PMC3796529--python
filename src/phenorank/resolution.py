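"""Hypothesis resolution: combining competing labeler outputs.

Seven labelers (five per-class dictionary matchers, the rule labeler and
the statistical tagger) each propose a BIO sequence per sentence.  Three
strategies turn those into one final sequence:

* **priority list** — union every proposed entity span (the non-entity
  label O never outranks an entity), then merge spans that share tokens
  into one span labeled with the highest-priority participating class.
  Default class order DS > PH > GG > AN > CD > OR > O.
* **maximum-entropy re-labeling** — re-label every token with a
  beam-decoded maximum-entropy classifier whose features are the current
  and context words plus every labeler's proposed tag (no ambiguity
  screening).
* **learn-to-rank re-ranking** — fix tokens where labelers agree, and for
  each ambiguous segment score the competing candidates with a pairwise
  large-margin linear ranker; the top candidate's tags are emitted.

A token is *ambiguous* when at least two distinct entity classes are
proposed for it; entity-versus-O differences alone are not conflicts (the
union rule settles them).  Ambiguous segments are maximal ambiguous runs
extended to the boundaries of every participating hypothesis span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.svm import LinearSVC

from .model import (
    O_TAG,
    CandidateSet,
    LabelSequence,
    repair_bio,
    tag_class,
    tags_to_token_spans,
    token_spans_to_tags,
)
from .tagger import (
    BeamConfig,
    FeatureTemplates,
    SentenceContext,
    TaggerModel,
    beam_decode,
    extract_features,
    train_tagger,
)

__all__ = [
    "DEFAULT_PRIORITY",
    "AmbiguityReport",
    "RankedCandidate",
    "RankQuery",
    "LTRModel",
    "detect_ambiguity",
    "resolve_priority",
    "resolution_context",
    "build_resolution_features",
    "train_me_resolver",
    "resolve_me",
    "segment_candidates",
    "build_rank_lists",
    "candidate_features",
    "train_ltr",
    "resolve_ltr",
]

#: Feature templates of the resolution models: current word, context words
#: and the labelers' proposed tags — no morphological (shape/prefix)
#: templates, which belong to the base tagger's feature set.
RESOLUTION_TEMPLATES = FeatureTemplates(use_shape=False)

#: Default total priority order, highest first; O always last.  Fragments
#: with direct ontological motivation: DS > PH, PH > GG, DS > OR, GG > OR
#: (organism names never contain a gene name); the rest of the order is a
#: configuration default.
DEFAULT_PRIORITY: tuple[str, ...] = ("DS", "PH", "GG", "AN", "CD", "OR", O_TAG)


def _check_priority(order: tuple[str, ...]) -> dict[str, int]:
    if order[-1] != O_TAG:
        raise ValueError("priority order must end with O")
    if len(set(order)) != len(order):
        raise ValueError("priority order has duplicates")
    return {cls: i for i, cls in enumerate(order)}


@dataclass
class AmbiguityReport:
    """Per-token ambiguity flags plus maximal ambiguous segments."""

    ambiguous: list[bool]
    segments: list[tuple[int, int]]  # token index ranges, half-open


def _hypothesis_spans(cs: CandidateSet) -> dict[str, list[tuple[int, int, str]]]:
    return {
        src: tags_to_token_spans(h.tags) for src, h in cs.hypotheses.items()
    }


def detect_ambiguity(candidate_set: CandidateSet) -> AmbiguityReport:
    """Flag tokens where >= 2 distinct entity classes are proposed.

    Disjoint proposals from different labelers (one says PH on "X Y",
    another GG on "W Z") are not conflicts: the union of the proposals is
    the agreed output.  Segments are maximal ambiguous runs, extended to
    cover every hypothesis span that touches them (to fixpoint).
    """
    n = candidate_set.n_tokens
    classes_at: list[set[str]] = [set() for _ in range(n)]
    for h in candidate_set.hypotheses.values():
        for t_i, tag in enumerate(repair_bio(h.tags)):
            cls = tag_class(tag)
            if cls is not None:
                classes_at[t_i].add(cls)
    ambiguous = [len(c) >= 2 for c in classes_at]
    # maximal runs
    segments: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if ambiguous[i]:
            j = i
            while j < n and ambiguous[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    # extend to participating span boundaries, to fixpoint, then merge
    spans = [sp for sps in _hypothesis_spans(candidate_set).values() for sp in sps]
    changed = True
    while changed:
        changed = False
        extended = []
        for s, e in segments:
            for ss, se, _ in spans:
                if ss < e and s < se:  # span touches segment
                    if ss < s or se > e:
                        s, e = min(s, ss), max(e, se)
                        changed = True
            extended.append((s, e))
        # merge overlapping segments
        extended.sort()
        merged: list[tuple[int, int]] = []
        for s, e in extended:
            if merged and s <= merged[-1][1]:
                if e > merged[-1][1]:
                    merged[-1] = (merged[-1][0], e)
                    changed = True
                else:
                    changed = changed or True
            else:
                merged.append((s, e))
        if len(merged) != len(segments):
            changed = True
        segments = merged
    return AmbiguityReport(ambiguous=ambiguous, segments=segments)


def resolve_priority(
    candidate_set: CandidateSet,
    priority_order: tuple[str, ...] = DEFAULT_PRIORITY,
) -> LabelSequence:
    """Priority-list resolution by union and merge.

    Stage 1: every proposed entity span is kept (O never outranks an
    entity).  Stage 2/3: spans sharing tokens — nested or partially
    overlapping — are merged into one span covering their union, labeled
    with the highest-priority participating class (so an embedded GG
    inside a PH yields the containing PH span, and [AB]_GG + [BC]_PH
    merge to [ABC]_PH).
    """
    rank = _check_priority(priority_order)
    spans = sorted(
        {sp for sps in _hypothesis_spans(candidate_set).values() for sp in sps}
    )
    changed = True
    while changed:
        changed = False
        out: list[tuple[int, int, str]] = []
        for sp in spans:
            merged = False
            for k, other in enumerate(out):
                if sp[0] < other[1] and other[0] < sp[1]:
                    cls = min(sp[2], other[2], key=lambda c: rank.get(c, len(rank)))
                    out[k] = (min(sp[0], other[0]), max(sp[1], other[1]), cls)
                    merged = True
                    changed = True
                    break
            if not merged:
                out.append(sp)
        spans = sorted(set(out))
    tags = token_spans_to_tags(spans, candidate_set.n_tokens)
    return LabelSequence(source="priority", tags=tuple(tags))


# ---------------------------------------------------------------------------
# Maximum-entropy re-labeling
# ---------------------------------------------------------------------------


def resolution_context(
    candidate_set: CandidateSet,
    tokens: list[str],
    expected_sources: tuple[str, ...] | None = None,
) -> SentenceContext:
    """Sentence context whose aux streams are the labeler hypotheses.

    Expected sources missing from the candidate set are substituted with
    an all-O stream (with a warning), so a model trained with a stream can
    still run when a labeler is disabled.
    """
    aux = {src: list(h.tags) for src, h in candidate_set.hypotheses.items()}
    if expected_sources:
        for src in expected_sources:
            if src not in aux:
                warnings.warn(
                    f"hypothesis stream {src!r} missing; substituting all-O",
                    stacklevel=2,
                )
                aux[src] = [O_TAG] * len(tokens)
    return SentenceContext(tokens=tokens, aux=aux)


def build_resolution_features(
    candidate_set: CandidateSet,
    tokens: list[str],
    position: int,
    prev_tags: tuple[str, ...] = (),
    templates: FeatureTemplates = RESOLUTION_TEMPLATES,
) -> dict[str, float]:
    """Resolution features at one position: current word, context words,
    and every labeler's proposed tag (windowed)."""
    return extract_features(
        resolution_context(candidate_set, tokens), position, prev_tags, templates
    )


def train_me_resolver(
    training: list[tuple[list[str], CandidateSet, tuple[str, ...]]],
    templates: FeatureTemplates = RESOLUTION_TEMPLATES,
    C: float = 10.0,
    seed: int = 0,
) -> TaggerModel:
    """Train the maximum-entropy resolution model.

    ``training`` triples are (sentence tokens, labeler hypotheses, gold
    tags).  Labeler outputs should be cross-fitted for any learned
    labeler, so the resolver sees realistic (not resubstituted) streams.
    """
    sources = sorted({s for _, cs, _ in training for s in cs.sources})
    rows = [
        (resolution_context(cs, toks, tuple(sources)), gold)
        for toks, cs, gold in training
    ]
    return train_tagger(rows, templates=templates, C=C, seed=seed)


def resolve_me(
    model: TaggerModel,
    candidate_set: CandidateSet,
    tokens: list[str],
    beam: BeamConfig = BeamConfig(),
    expected_sources: tuple[str, ...] | None = None,
) -> LabelSequence:
    """Full re-labeling of every token (no ambiguity screening)."""
    ctx = resolution_context(candidate_set, tokens, expected_sources)
    seq = beam_decode(model, ctx, beam, source="me_resolver")
    return seq


# ---------------------------------------------------------------------------
# Learn-to-rank re-ranking
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RankedCandidate:
    """One labeler's tag assignment over an ambiguous segment.

    ``tier`` is the heuristic rank rule that applied (1 = exact agreement
    with the annotation, 2 = partial overlap in tag assignment, 3 = no
    overlap); ``rank`` is the candidate's position in the query's total
    order (1 best) after the left-position and source-name tie-breaks.
    """

    query_id: str
    source: str
    tags: tuple[str, ...]
    tier: int = 0
    rank: int = 0


@dataclass
class RankQuery:
    query_id: str
    segment: tuple[int, int]
    candidates: list[RankedCandidate] = field(default_factory=list)


def segment_candidates(
    candidate_set: CandidateSet, segment: tuple[int, int]
) -> list[tuple[str, tuple[str, ...]]]:
    """Distinct candidate tag assignments over a segment.

    Each labeler contributes its (locally repaired) tags; identical
    assignments are deduplicated keeping the lexicographically first
    source name.
    """
    s, e = segment
    seen: dict[tuple[str, ...], str] = {}
    for src in sorted(candidate_set.hypotheses):
        local = tuple(repair_bio(repair_bio(candidate_set.hypotheses[src].tags)[s:e]))
        if local not in seen:
            seen[local] = src
    return sorted(((src, tags) for tags, src in seen.items()), key=lambda x: x[0])


def _tier_and_left(
    cand_tags: tuple[str, ...], gold_local: tuple[str, ...]
) -> tuple[int, int]:
    cand_spans = tags_to_token_spans(cand_tags)
    gold_spans = tags_to_token_spans(gold_local)
    if set(cand_spans) == set(gold_spans):
        left = cand_spans[0][0] if cand_spans else 0
        return 1, left
    # overlap in tag assignment is span overlap, regardless of class
    overlaps = [
        cs
        for cs in cand_spans
        for gs in gold_spans
        if cs[0] < gs[1] and gs[0] < cs[1]
    ]
    if overlaps:
        return 2, min(o[0] for o in overlaps)
    return 3, len(cand_tags)


def build_rank_lists(
    candidate_set: CandidateSet,
    gold_tags: tuple[str, ...] | list[str],
    report: AmbiguityReport | None = None,
) -> list[RankQuery]:
    """Training rank lists, one query per ambiguous segment.

    Three heuristic rules order the candidates against the annotation:
    exact class+span agreement ranks first, partial overlap in tag
    assignment second, no overlap last.  Within the first two tiers,
    candidates whose match starts further left rank higher (the sequence
    is processed left to right); residual ties break on source name.
    """
    if report is None:
        report = detect_ambiguity(candidate_set)
    queries: list[RankQuery] = []
    for s, e in report.segments:
        cands = segment_candidates(candidate_set, (s, e))
        if not cands:
            warnings.warn(f"no candidates for segment ({s},{e}); query dropped")
            continue
        gold_local = tuple(repair_bio(list(gold_tags[s:e])))
        qid = f"seg{s}-{e}"
        keyed = []
        for src, tags in cands:
            tier, left = _tier_and_left(tags, gold_local)
            keyed.append((tier, left, src, tags))
        keyed.sort(key=lambda k: (k[0], k[1], k[2]))
        query = RankQuery(query_id=qid, segment=(s, e))
        for pos, (tier, _left, src, tags) in enumerate(keyed, start=1):
            query.candidates.append(
                RankedCandidate(
                    query_id=qid, source=src, tags=tags, tier=tier, rank=pos
                )
            )
        queries.append(query)
    return queries


def candidate_features(
    candidate_set: CandidateSet,
    tokens: list[str],
    segment: tuple[int, int],
    cand_tags: tuple[str, ...],
    window: int = 2,
) -> dict[str, float]:
    """Sparse features describing one candidate over one segment.

    Conjunctions of the candidate's tags with the words and with every
    labeler's proposed tag, plus class-context features pairing the
    candidate's leading entity class with the words surrounding the
    segment — the signal that lets the ranker prefer e.g. PH over DS when
    the context says "...phenotypes".
    """
    s, e = segment
    feats: dict[str, float] = {}
    for i in range(e - s):
        g = s + i
        t = cand_tags[i]
        feats[f"t={t}"] = feats.get(f"t={t}", 0.0) + 1.0
        fw = f"t={t}|w={tokens[g].lower()}"
        feats[fw] = feats.get(fw, 0.0) + 1.0
        for src, h in candidate_set.hypotheses.items():
            fh = f"t={t}|{src}={h.tags[g]}"
            feats[fh] = feats.get(fh, 0.0) + 1.0
    classes = [c for c in (tag_class(t) for t in cand_tags) if c]
    lead = classes[0] if classes else O_TAG
    feats[f"lead={lead}"] = 1.0
    n = len(tokens)
    for off in range(-window, 0):
        j = s + off
        w = tokens[j].lower() if 0 <= j < n else "<S>"
        feats[f"lead={lead}|ctx[{off}]={w}"] = 1.0
    for off in range(0, window):
        j = e + off
        w = tokens[j].lower() if 0 <= j < n else "</S>"
        feats[f"lead={lead}|ctx[+{off + 1}]={w}"] = 1.0
    return feats


@dataclass
class LTRModel:
    """Pairwise large-margin linear ranking model over candidate features."""

    vectorizer: DictVectorizer | None = None
    coef: np.ndarray | None = None

    @property
    def trained(self) -> bool:
        return self.coef is not None

    def score(self, feats: dict[str, float]) -> float:
        if not self.trained:
            raise ValueError("LTR model not trained")
        X = self.vectorizer.transform([feats])
        return float((X @ self.coef)[0])


def train_ltr(
    queries: list[tuple[RankQuery, list[dict[str, float]]]],
    C: float = 1.0,
    seed: int = 0,
) -> LTRModel:
    """Train the ranker from rank lists with per-candidate features.

    For every query and every candidate pair with tier(a) < tier(b) the
    learner receives the margin constraint score(a) > score(b), fit as a
    linear SVM on pairwise feature differences.  Features unseen at
    inference are simply absent from the sparse vector (and ignored).
    """
    all_feats = [f for _, feats in queries for f in feats]
    if not all_feats:
        return LTRModel()
    vec = DictVectorizer(sparse=True)
    vec.fit(all_feats)
    rows = []
    ys = []
    for query, feats in queries:
        X = vec.transform(feats)
        for i, a in enumerate(query.candidates):
            for j, b in enumerate(query.candidates):
                if a.tier < b.tier:
                    d = X[i] - X[j]
                    rows.append(d)
                    ys.append(1)
                    rows.append(-d)
                    ys.append(-1)
    if not rows:
        return LTRModel()
    import scipy.sparse as sp

    Xp = sp.vstack(rows)
    clf = LinearSVC(
        C=C, fit_intercept=False, dual=False, random_state=seed, max_iter=5000
    )
    clf.fit(Xp, ys)
    return LTRModel(vectorizer=vec, coef=clf.coef_.ravel())


def resolve_ltr(
    model: LTRModel,
    candidate_set: CandidateSet,
    tokens: list[str],
    report: AmbiguityReport | None = None,
    priority_order: tuple[str, ...] = DEFAULT_PRIORITY,
) -> LabelSequence:
    """Learn-to-rank resolution.

    Unambiguous tokens take the agreed (union) output with no further
    processing.  Per ambiguous segment the candidates are scored with the
    learned linear function and the top candidate's tags are emitted; a
    single-candidate segment passes through unchanged, and an untrained
    model falls back to the priority list for conflicting segments.
    """
    if report is None:
        report = detect_ambiguity(candidate_set)
    base = list(resolve_priority(candidate_set, priority_order).tags)
    for seg in report.segments:
        cands = segment_candidates(candidate_set, seg)
        if not cands:
            continue
        if len(cands) == 1:
            chosen = cands[0][1]
        elif model.trained:
            scored = []
            for src, tags in cands:
                f = candidate_features(candidate_set, tokens, seg, tags)
                scored.append((-model.score(f), tags, src))
            scored.sort()
            chosen = scored[0][1]
        else:
            continue  # keep priority-list output for this segment
        base[seg[0] : seg[1]] = list(chosen)
    return LabelSequence(source="ltr", tags=tuple(repair_bio(base)))
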