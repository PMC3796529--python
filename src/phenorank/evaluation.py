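"""Span-matching evaluation, cross-validation, unique-mention analysis,
and approximate-randomization significance testing.

A predicted mention counts as a true positive when it pairs one-to-one
with an unmatched gold mention of the same class whose span *partially
overlaps* it (mode ``partial``) or exactly equals it (mode ``exact``).
Precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean
(reported x100); micro-averages pool TP/FP/FN over classes before
computing P/R/F.

System comparison uses approximate randomization: per repetition each
sentence's two system outputs are randomly swapped between two
pseudo-systems, and the p-value is the fraction of repetitions whose
pseudo micro-F difference is at least the observed difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Document, Mention
from .pipeline import HybridNER, SystemConfig

__all__ = [
    "ClassCounts",
    "EvalCounts",
    "PRF",
    "RandomizationConfig",
    "match_mentions",
    "compute_prf",
    "f1_score",
    "micro_average",
    "FoldResult",
    "SentenceOutput",
    "cross_validate",
    "unique_mention_eval",
    "approx_randomization",
]


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "ClassCounts") -> "ClassCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


@dataclass
class EvalCounts:
    """Per-class TP/FP/FN tallies under one matching mode."""

    mode: str = "partial"
    per_class: dict[str, ClassCounts] = field(default_factory=dict)

    def cls(self, entity_class: str) -> ClassCounts:
        return self.per_class.setdefault(entity_class, ClassCounts())

    def add(self, other: "EvalCounts") -> "EvalCounts":
        if other.mode != self.mode:
            raise ValueError("cannot pool counts across matching modes")
        for c, counts in other.per_class.items():
            self.cls(c).__iadd__(counts)
        return self

    def totals(self) -> ClassCounts:
        t = ClassCounts()
        for counts in self.per_class.values():
            t += counts
        return t


@dataclass(frozen=True)
class PRF:
    """Precision/recall/F1 on the 0–1 scale (multiply by 100 to report)."""

    precision: float
    recall: float
    f1: float

    def scaled(self) -> tuple[float, float, float]:
        return (
            round(100 * self.precision, 1),
            round(100 * self.recall, 1),
            round(100 * self.f1, 1),
        )


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def _spans_match(g: Mention, p: Mention, mode: str) -> bool:
    if mode == "exact":
        return g.start == p.start and g.end == p.end
    if mode == "partial":
        return g.start < p.end and p.start < g.end
    raise ValueError(f"unknown matching mode {mode!r}")


def match_mentions(
    gold_mentions: list[Mention],
    predicted_mentions: list[Mention],
    mode: str = "partial",
) -> EvalCounts:
    """Greedy one-to-one matching with per-class pools.

    Predictions are visited left to right; each pairs with the first
    unmatched gold mention of the same class whose span matches under the
    mode.  One-to-one pairing prevents a single long prediction from
    matching several gold mentions.
    """
    counts = EvalCounts(mode=mode)
    classes = {m.entity_class for m in gold_mentions} | {
        m.entity_class for m in predicted_mentions
    }
    for cls in classes:
        gold = sorted(m for m in gold_mentions if m.entity_class == cls)
        preds = sorted(m for m in predicted_mentions if m.entity_class == cls)
        used = [False] * len(gold)
        cc = counts.cls(cls)
        for p in preds:
            hit = None
            for gi, g in enumerate(gold):
                if not used[gi] and _spans_match(g, p, mode):
                    hit = gi
                    break
            if hit is None:
                cc.fp += 1
            else:
                used[hit] = True
                cc.tp += 1
        cc.fn += used.count(False)
    return counts


def compute_prf(eval_counts: EvalCounts) -> dict[str, PRF]:
    """Per-class precision/recall/F1 (zero-denominator convention: 0)."""
    out = {}
    for cls, c in eval_counts.per_class.items():
        p = c.tp / (c.tp + c.fp) if c.tp + c.fp else 0.0
        r = c.tp / (c.tp + c.fn) if c.tp + c.fn else 0.0
        out[cls] = PRF(p, r, f1_score(p, r))
    return out


def micro_average(eval_counts: EvalCounts) -> PRF:
    """PRF from TP/FP/FN summed over all classes."""
    t = eval_counts.totals()
    p = t.tp / (t.tp + t.fp) if t.tp + t.fp else 0.0
    r = t.tp / (t.tp + t.fn) if t.tp + t.fn else 0.0
    return PRF(p, r, f1_score(p, r))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class SentenceOutput:
    """Predictions and gold for one sentence (unit of the significance test)."""

    doc_id: str
    sentence_index: int
    gold: list[Mention]
    predicted: list[Mention]


@dataclass
class FoldResult:
    fold: int
    train_doc_ids: list[str]
    test_doc_ids: list[str]
    counts: EvalCounts
    sentence_outputs: list[SentenceOutput]
    train_gold: list[Mention] = field(default_factory=list)
    test_doc_gold: dict[str, list[Mention]] = field(default_factory=dict)
    test_doc_pred: dict[str, list[Mention]] = field(default_factory=dict)


def cross_validate(
    corpus: list[Document],
    config: SystemConfig,
    k: int = 10,
    seed: int = 0,
    mode: str = "partial",
) -> tuple[list[FoldResult], EvalCounts]:
    """Document-level k-fold cross-validation of the full system.

    The corpus is partitioned into k near-equal folds (seeded shuffle);
    each fold is tagged by a system trained on the other k-1, and
    TP/FP/FN are pooled over folds before computing PRF.  The fold unit
    is the document (abstract), preventing within-abstract leakage.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(corpus) < k:
        raise ValueError(f"corpus has {len(corpus)} documents < k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    folds = [sorted(order[i::k]) for i in range(k)]
    results: list[FoldResult] = []
    pooled = EvalCounts(mode=mode)
    for fi, fold in enumerate(folds):
        held = set(fold)
        train_docs = [d for j, d in enumerate(corpus) if j not in held]
        test_docs = [corpus[j] for j in fold]
        system = HybridNER(config).fit(train_docs)
        counts = EvalCounts(mode=mode)
        sent_outputs = []
        doc_gold = {}
        doc_pred = {}
        for doc in test_docs:
            pred = system.predict_mentions(doc)
            doc_gold[doc.id] = list(doc.gold_mentions)
            doc_pred[doc.id] = pred
            counts.add(match_mentions(doc.gold_mentions, pred, mode))
            for i in range(doc.n_sentences):
                s, e = doc.sentences[i]
                sent_outputs.append(
                    SentenceOutput(
                        doc_id=doc.id,
                        sentence_index=i,
                        gold=[
                            m
                            for m in doc.gold_mentions
                            if s <= m.start and m.end <= e
                        ],
                        predicted=[
                            m for m in pred if s <= m.start and m.end <= e
                        ],
                    )
                )
        results.append(
            FoldResult(
                fold=fi,
                train_doc_ids=[d.id for d in train_docs],
                test_doc_ids=[d.id for d in test_docs],
                counts=counts,
                sentence_outputs=sent_outputs,
                train_gold=[m for d in train_docs for m in d.gold_mentions],
                test_doc_gold=doc_gold,
                test_doc_pred=doc_pred,
            )
        )
        pooled.add(counts)
    return results, pooled


def _norm_surface(m: Mention) -> tuple[str, str]:
    return (" ".join(m.surface.lower().split()), m.entity_class)


def unique_mention_eval(
    fold_results: list[FoldResult], mode: str = "partial"
) -> tuple[dict[str, PRF], dict[str, float], EvalCounts]:
    """Performance on unique mentions only, plus per-class unique rates.

    A test gold mention is *unique* in its fold when its normalized
    (surface, class) never occurs as a gold mention in that fold's
    training documents.  PRF is computed with gold restricted to unique
    mentions; predictions that partially match a non-unique gold mention
    of the same class are excluded (they are credited to seen mentions).
    Unique rate = unique gold / total gold x100, pooled over folds.
    """
    pooled = EvalCounts(mode=mode)
    unique_count: dict[str, int] = {}
    total_count: dict[str, int] = {}
    for fr in fold_results:
        train_keys = {_norm_surface(m) for m in fr.train_gold}
        for doc_id, gold in fr.test_doc_gold.items():
            preds = fr.test_doc_pred[doc_id]
            unique_gold = [m for m in gold if _norm_surface(m) not in train_keys]
            seen_gold = [m for m in gold if _norm_surface(m) in train_keys]
            for m in gold:
                total_count[m.entity_class] = total_count.get(m.entity_class, 0) + 1
            for m in unique_gold:
                unique_count[m.entity_class] = (
                    unique_count.get(m.entity_class, 0) + 1
                )
            kept_preds = [
                p
                for p in preds
                if not any(
                    g.entity_class == p.entity_class and _spans_match(g, p, mode)
                    for g in seen_gold
                )
            ]
            pooled.add(match_mentions(unique_gold, kept_preds, mode))
    rates = {
        cls: round(100 * unique_count.get(cls, 0) / total_count[cls], 1)
        for cls in total_count
    }
    return compute_prf(pooled), rates, pooled


# ---------------------------------------------------------------------------
# Approximate randomization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomizationConfig:
    repetitions: int = 1000
    seed: int = 0
    method: str = "resample"  # or "exhaustive" (all 2^n swap patterns)

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.method not in ("resample", "exhaustive"):
            raise ValueError(f"unknown method {self.method!r}")


def _micro_f_from_counts(counts: np.ndarray) -> float:
    tp, fp, fn = counts
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return f1_score(p, r)


def approx_randomization(
    outputs_a: list[list[Mention]],
    outputs_b: list[list[Mention]],
    gold: list[list[Mention]],
    config: RandomizationConfig = RandomizationConfig(),
    mode: str = "partial",
) -> dict:
    """Approximate-randomization significance test between two systems.

    Step 1 computes the observed micro-F difference delta = F_A - F_B
    over the pooled sentences.  Each repetition randomly reassigns every
    sentence's two outputs between two pseudo-systems (a paired
    sentence-level swap) and records the pseudo difference; the p-value
    is #(pseudo-delta >= delta) / repetitions.  ``method='exhaustive'``
    enumerates all 2^n swap patterns instead (n <= 20).

    Returns a report dict with delta, p, repetitions, and the seed.
    """
    if not (len(outputs_a) == len(outputs_b) == len(gold)):
        raise ValueError("A, B and gold must cover the same sentences")
    n = len(gold)
    a_counts = np.zeros((n, 3))
    b_counts = np.zeros((n, 3))
    for i in range(n):
        ca = match_mentions(gold[i], outputs_a[i], mode).totals()
        cb = match_mentions(gold[i], outputs_b[i], mode).totals()
        a_counts[i] = (ca.tp, ca.fp, ca.fn)
        b_counts[i] = (cb.tp, cb.fp, cb.fn)
    delta = _micro_f_from_counts(a_counts.sum(axis=0)) - _micro_f_from_counts(
        b_counts.sum(axis=0)
    )

    def pseudo_delta(mask: np.ndarray) -> float:
        m = mask[:, None]
        x = np.where(m, b_counts, a_counts).sum(axis=0)
        y = np.where(m, a_counts, b_counts).sum(axis=0)
        return _micro_f_from_counts(x) - _micro_f_from_counts(y)

    if config.method == "exhaustive":
        if n > 20:
            raise ValueError("exhaustive enumeration limited to n <= 20 sentences")
        reps = 2**n
        hits = 0
        for bits in range(reps):
            mask = np.array([(bits >> i) & 1 for i in range(n)], dtype=bool)
            if pseudo_delta(mask) >= delta:
                hits += 1
    else:
        reps = config.repetitions
        rng = np.random.default_rng(config.seed)
        hits = 0
        for _ in range(reps):
            mask = rng.random(n) < 0.5
            if pseudo_delta(mask) >= delta:
                hits += 1
    return {
        "delta": delta,
        "p": hits / reps,
        "repetitions": reps,
        "seed": config.seed,
        "method": config.method,
        "n_sentences": n,
        "mode": mode,
    }
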