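"""Supervised sequence labeler: per-token maximum-entropy classification
decoded with beam search.

Each token position is classified by a multinomial logistic-regression
(maximum entropy) model over sparse lexical features — focus word,
surrounding context words in a +/-2 window, auxiliary per-token tag
streams (part of speech, species tags, an external tagger's labels) and
the previously assigned tags.  Because the previous-tag features couple
decisions along the sentence, decoding keeps the K highest-scoring tag
prefixes (beam search, default K=3) instead of exact dynamic programming;
complexity is linear in sentence length x labels x K.

An exhaustive enumeration decoder is provided as a test oracle: at
saturated K the beam recovers the true maximum-score sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.feature_extraction import DictVectorizer
from sklearn.linear_model import LogisticRegression

from .model import Document, LabelSequence, repair_bio

__all__ = [
    "SentenceContext",
    "FeatureTemplates",
    "BeamConfig",
    "TaggerModel",
    "extract_features",
    "doc_contexts",
    "train_tagger",
    "beam_search",
    "beam_decode",
    "exhaustive_decode",
]

_PAD = "<S>"


def _word_shape(word: str) -> str:
    """Collapsed character shape: letters->a/A, digits->0, runs deduped."""
    shape = []
    for c in word:
        s = "A" if c.isupper() else "a" if c.islower() else "0" if c.isdigit() else c
        if not shape or shape[-1] != s:
            shape.append(s)
    return "".join(shape)

MODEL_FORMAT_VERSION = 1


@dataclass
class SentenceContext:
    """Tokens of one sentence plus aligned auxiliary tag columns."""

    tokens: list[str]
    aux: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, col in self.aux.items():
            if len(col) != len(self.tokens):
                raise ValueError(f"aux stream {name!r} misaligned")


@dataclass(frozen=True)
class FeatureTemplates:
    """Feature template configuration for the per-token classifier."""

    window: int = 2        # context words at offsets -window..window
    prev_tags: int = 2     # previously assigned tags used as features
    use_aux: bool = True   # include aux tag streams, windowed like words
    use_shape: bool = True  # focus-word prefix and character-shape features


@dataclass(frozen=True)
class BeamConfig:
    width: int = 3

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("beam width must be >= 1")


def extract_features(
    context: SentenceContext,
    position: int,
    prev_tags: tuple[str, ...],
    templates: FeatureTemplates = FeatureTemplates(),
) -> dict[str, float]:
    """Deterministic template expansion at one token position.

    ``prev_tags`` holds the tags already assigned to positions
    ``0..position-1`` (gold during training, hypothesised during
    decoding); absent window slots use boundary padding symbols.
    """
    toks = context.tokens
    n = len(toks)
    feats: dict[str, float] = {}
    for off in range(-templates.window, templates.window + 1):
        j = position + off
        w = toks[j] if 0 <= j < n else _PAD
        feats[f"w[{off}]={w.lower()}"] = 1.0
        if templates.use_shape and 0 <= j < n:
            lw = w.lower()
            feats[f"pre2[{off}]={lw[:2]}"] = 1.0
            feats[f"pre3[{off}]={lw[:3]}"] = 1.0
            feats[f"shape[{off}]={_word_shape(w)}"] = 1.0
    if templates.use_aux:
        for name in sorted(context.aux):
            col = context.aux[name]
            for off in range(-templates.window, templates.window + 1):
                j = position + off
                t = col[j] if 0 <= j < n else _PAD
                feats[f"aux:{name}[{off}]={t}"] = 1.0
    for k in range(1, templates.prev_tags + 1):
        j = position - k
        t = prev_tags[j] if j >= 0 else _PAD
        feats[f"prev[-{k}]={t}"] = 1.0
    return feats


def doc_contexts(
    document: Document, extra_aux: dict[str, list[list[str]]] | None = None
) -> list[SentenceContext]:
    """Per-sentence contexts from a document's tokens and aux streams."""
    out = []
    for i in range(document.n_sentences):
        aux = {name: s[i] for name, s in document.aux_streams.items()}
        if extra_aux:
            for name, s in extra_aux.items():
                aux[name] = s[i]
        out.append(SentenceContext(tokens=document.token_texts(i), aux=aux))
    return out


class _ConstantModel:
    """Degenerate classifier for single-label training data."""

    def __init__(self, label: str) -> None:
        self.classes_ = np.array([label])

    def predict_log_proba(self, X) -> np.ndarray:
        return np.zeros((X.shape[0], 1))


@dataclass
class TaggerModel:
    """A trained maximum-entropy token classifier plus its feature config.

    Per position the model yields a normalized probability distribution
    over its label inventory, conditioned on the sentence context and the
    previously assigned tags.
    """

    labels: tuple[str, ...]
    vectorizer: DictVectorizer
    clf: object
    templates: FeatureTemplates

    def log_probs(
        self,
        context: SentenceContext,
        position: int,
        prev_tags: tuple[str, ...],
    ) -> np.ndarray:
        """Log p(label | context, position, prev_tags), aligned with
        ``self.labels`` (lexicographically sorted)."""
        feats = extract_features(context, position, prev_tags, self.templates)
        X = self.vectorizer.transform([feats])
        return self.clf.predict_log_proba(X)[0]

    def save(self, path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": self}, path)

    @staticmethod
    def load(path) -> "TaggerModel":
        payload = joblib.load(path)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format: {payload.get('format_version')}"
            )
        return payload["model"]


def train_tagger(
    training: list[tuple[SentenceContext, tuple[str, ...]]],
    templates: FeatureTemplates = FeatureTemplates(),
    C: float = 10.0,
    seed: int = 0,
    expected_labels: tuple[str, ...] | None = None,
    max_iter: int = 200,
) -> TaggerModel:
    """Fit the per-position label classifier by regularized maximum
    likelihood (L2, strength ``1/C``); deterministic given the seed.

    ``training`` pairs each sentence context with its gold tags;
    previous-tag features are taken from gold.  Labels expected by the
    caller but absent from the training data are reported with a warning;
    the model's inventory is what it observed.
    """
    if not training:
        raise ValueError("no training sentences")
    rows: list[dict[str, float]] = []
    ys: list[str] = []
    for ctx, gold in training:
        if len(gold) != len(ctx.tokens):
            raise ValueError("gold tag length mismatch")
        for pos in range(len(ctx.tokens)):
            rows.append(extract_features(ctx, pos, tuple(gold[:pos]), templates))
            ys.append(gold[pos])
    observed = tuple(sorted(set(ys)))
    if expected_labels:
        missing = sorted(set(expected_labels) - set(observed))
        if missing:
            warnings.warn(
                f"labels absent from training data: {missing}", stacklevel=2
            )
    vectorizer = DictVectorizer(sparse=True)
    X = vectorizer.fit_transform(rows)
    if len(observed) == 1:
        clf: object = _ConstantModel(observed[0])
    else:
        clf = LogisticRegression(
            C=C, max_iter=max_iter, solver="lbfgs", random_state=seed
        )
        clf.fit(X, ys)
    labels = tuple(str(c) for c in clf.classes_)  # sklearn sorts classes
    return TaggerModel(
        labels=labels, vectorizer=vectorizer, clf=clf, templates=templates
    )


def beam_search(
    model: TaggerModel, context: SentenceContext, beam: BeamConfig = BeamConfig()
) -> tuple[tuple[str, ...], float]:
    """Beam-search decoding: keep the K best-scoring tag prefixes.

    Score is the sum of per-position log-probabilities.  Ties are broken
    toward the lexicographically smaller tag sequence, both when pruning
    and when selecting the final sequence, so saturated-K beam search
    agrees exactly with :func:`exhaustive_decode`.
    """
    n = len(context.tokens)
    if n == 0:
        return (), 0.0
    beams: list[tuple[float, tuple[str, ...]]] = [(0.0, ())]
    for pos in range(n):
        expanded: list[tuple[float, tuple[str, ...]]] = []
        for score, prefix in beams:
            lp = model.log_probs(context, pos, prefix)
            for li, lab in enumerate(model.labels):
                expanded.append((score + lp[li], prefix + (lab,)))
        expanded.sort(key=lambda sp: (-sp[0], sp[1]))
        beams = expanded[: beam.width]
    best_score, best_tags = beams[0]
    return best_tags, best_score


def beam_decode(
    model: TaggerModel,
    context: SentenceContext,
    beam: BeamConfig = BeamConfig(),
    source: str = "me_bs",
) -> LabelSequence:
    """Decode one sentence and repair the result to well-formed BIO."""
    tags, _ = beam_search(model, context, beam)
    return LabelSequence(source=source, tags=tuple(repair_bio(tags)))


def exhaustive_decode(
    model: TaggerModel, context: SentenceContext, limit: int = 10**6
) -> tuple[tuple[str, ...], float]:
    """True maximum-score sequence by depth-first enumeration (test oracle).

    Enumerates sequences in lexicographic tag order and keeps the first
    maximum, matching the beam decoder's tie rule.  Refuses search spaces
    larger than ``limit`` sequences.
    """
    n = len(context.tokens)
    if n == 0:
        return (), 0.0
    if len(model.labels) ** n > limit:
        raise ValueError(
            f"search space {len(model.labels)}^{n} exceeds limit {limit}"
        )
    best: list[tuple[float, tuple[str, ...]] | None] = [None]

    def dfs(prefix: tuple[str, ...], score: float) -> None:
        pos = len(prefix)
        if pos == n:
            if best[0] is None or score > best[0][0]:
                best[0] = (score, prefix)
            return
        lp = model.log_probs(context, pos, prefix)
        for li, lab in enumerate(model.labels):
            dfs(prefix + (lab,), score + lp[li])

    dfs((), 0.0)
    assert best[0] is not None
    return best[0][1], best[0][0]
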