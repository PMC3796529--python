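"""The assembled hybrid NER system and its configuration.

The full configuration runs seven labelers per sentence — one
dictionary matcher per entity class (PH, DS, CD, AN, GG), the
modifier-composition rule labeler, and the maximum-entropy sequence
tagger — and resolves their conflicting hypotheses with a selectable
strategy (priority list, maximum-entropy re-labeling, or learn-to-rank).

Every external resource (each lexicon source, the rule labeler, the
statistical tagger, each aux feature stream) is registered by name and
can be knocked out for ablation studies without touching anything else.

When a learned resolver is trained, the statistical tagger's outputs on
its own training documents are *cross-fitted* (predicted by models
trained on held-out folds within the training partition) so the resolver
sees realistic rather than resubstituted label streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .lexicon import Lexicon, ModifierList, dict_label, rule_label
from .model import (
    O_TAG,
    CandidateSet,
    DEFAULT_CLASSES,
    Document,
    LabelSequence,
    Mention,
    bio_labels,
    bio_to_mentions,
)
from .resolution import (
    DEFAULT_PRIORITY,
    RESOLUTION_TEMPLATES,
    LTRModel,
    build_rank_lists,
    candidate_features,
    resolve_ltr,
    resolve_me,
    resolve_priority,
    train_ltr,
    train_me_resolver,
)
from .tagger import (
    BeamConfig,
    FeatureTemplates,
    SentenceContext,
    TaggerModel,
    beam_decode,
    train_tagger,
)

__all__ = ["SystemConfig", "HybridNER", "ablate", "registered_resources"]

RULE_LABELER = "rule"
ME_LABELER = "me_bs"


@dataclass(frozen=True)
class SystemConfig:
    """Configuration of the full system.

    ``lexicons`` is the resource registry: any number of named term lists,
    each tied to an entity class; enabled lexicons of the same class merge
    into that class's dictionary labeler (mirroring e.g. HPO+MP+PATO all
    feeding the PH dictionary).
    """

    lexicons: tuple[Lexicon, ...] = ()
    modifiers: ModifierList | None = None
    rule_head_classes: tuple[str, ...] = ("AN", "GG", "DS")
    use_tagger: bool = True
    aux_resources: tuple[str, ...] = ()
    classes: tuple[str, ...] = DEFAULT_CLASSES
    resolver: str = "priority"
    priority_order: tuple[str, ...] = DEFAULT_PRIORITY
    beam: BeamConfig = BeamConfig(3)
    templates: FeatureTemplates = FeatureTemplates()
    resolver_templates: FeatureTemplates = RESOLUTION_TEMPLATES
    tagger_C: float = 10.0
    resolver_C: float = 1.0
    crossfit_folds: int = 3
    seed: int = 0
    disabled: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.resolver not in ("priority", "me", "ltr"):
            raise ValueError(f"unknown resolver {self.resolver!r}")
        sources = [lx.source for lx in self.lexicons]
        if len(set(sources)) != len(sources):
            raise ValueError("lexicon source names must be unique")


def registered_resources(config: SystemConfig) -> tuple[str, ...]:
    names = [lx.source for lx in config.lexicons]
    names.append(RULE_LABELER)
    names.append(ME_LABELER)
    names.extend(config.aux_resources)
    return tuple(names)


def ablate(config: SystemConfig, resource_name: str) -> SystemConfig:
    """Return a configuration with one named resource knocked out."""
    registered = registered_resources(config)
    if resource_name not in registered:
        raise KeyError(
            f"unknown resource {resource_name!r}; registered: {sorted(registered)}"
        )
    return replace(config, disabled=config.disabled | {resource_name})


def restore(config: SystemConfig, resource_name: str) -> SystemConfig:
    return replace(config, disabled=config.disabled - {resource_name})


class HybridNER:
    """Seven-labeler hybrid recognizer with pluggable hypothesis resolution."""

    def __init__(self, config: SystemConfig) -> None:
        self.config = config
        self.tagger: TaggerModel | None = None
        self.me_resolver: TaggerModel | None = None
        self.ltr_model: LTRModel | None = None
        self._me_sources: tuple[str, ...] = ()

    # -- labeler streams ----------------------------------------------------

    def class_lexicons(self) -> dict[str, Lexicon]:
        merged: dict[str, Lexicon] = {}
        for lx in self.config.lexicons:
            if lx.source in self.config.disabled:
                continue
            if lx.entity_class in merged:
                merged[lx.entity_class] = merged[lx.entity_class].merge(lx)
            else:
                merged[lx.entity_class] = lx
        return merged

    def _enabled_aux(self, document: Document) -> dict[str, list[list[str]]]:
        return {
            name: stream
            for name, stream in document.aux_streams.items()
            if name not in self.config.disabled
        }

    def _contexts(self, document: Document) -> list[SentenceContext]:
        aux = self._enabled_aux(document)
        return [
            SentenceContext(
                tokens=document.token_texts(i),
                aux={name: stream[i] for name, stream in aux.items()},
            )
            for i in range(document.n_sentences)
        ]

    def candidate_sets(
        self,
        document: Document,
        tagger_outputs: list[LabelSequence] | None = None,
        tagger: TaggerModel | None = None,
    ) -> list[CandidateSet]:
        """Run every enabled labeler on each sentence of a document.

        ``tagger_outputs`` lets callers substitute externally computed
        (e.g. cross-fitted) statistical-tagger streams.
        """
        cfg = self.config
        lexicons = self.class_lexicons()
        tagger = tagger if tagger is not None else self.tagger
        contexts = self._contexts(document)
        out = []
        for i in range(document.n_sentences):
            toks = document.token_texts(i)
            hyps: dict[str, LabelSequence] = {}
            for cls in sorted(lexicons):
                name = f"dict_{cls}"
                hyps[name] = LabelSequence(
                    source=name, tags=tuple(dict_label(toks, lexicons[cls]))
                )
            if cfg.modifiers is not None and RULE_LABELER not in cfg.disabled:
                heads = {
                    c: lexicons[c]
                    for c in cfg.rule_head_classes
                    if c in lexicons
                }
                if heads:
                    hyps[RULE_LABELER] = LabelSequence(
                        source=RULE_LABELER,
                        tags=tuple(rule_label(toks, cfg.modifiers, heads)),
                    )
            if cfg.use_tagger and ME_LABELER not in cfg.disabled:
                if tagger_outputs is not None:
                    seq = tagger_outputs[i]
                    hyps[ME_LABELER] = LabelSequence(ME_LABELER, seq.tags)
                elif tagger is not None:
                    seq = beam_decode(
                        tagger, contexts[i], cfg.beam, source=ME_LABELER
                    )
                    hyps[ME_LABELER] = seq
            if not hyps:
                hyps[O_TAG] = LabelSequence(O_TAG, tuple([O_TAG] * len(toks)))
            out.append(CandidateSet(sentence_index=i, hypotheses=hyps))
        return out

    # -- training -----------------------------------------------------------

    def _tagger_training_rows(
        self, documents: list[Document]
    ) -> list[tuple[SentenceContext, tuple[str, ...]]]:
        rows = []
        for doc in documents:
            ctxs = self._contexts(doc)
            for i in range(doc.n_sentences):
                rows.append((ctxs[i], doc.gold_bio(i).tags))
        return rows

    def _train_base_tagger(self, documents: list[Document]) -> TaggerModel:
        return train_tagger(
            self._tagger_training_rows(documents),
            templates=self.config.templates,
            C=self.config.tagger_C,
            seed=self.config.seed,
            expected_labels=bio_labels(self.config.classes),
        )

    def crossfit_tagger_outputs(
        self, documents: list[Document]
    ) -> dict[str, list[LabelSequence]]:
        """Held-out statistical-tagger predictions for training documents."""
        cfg = self.config
        k = min(cfg.crossfit_folds, len(documents))
        outputs: dict[str, list[LabelSequence]] = {}
        if k < 2:
            warnings.warn(
                "cross-fitting needs >= 2 documents; using resubstitution",
                stacklevel=2,
            )
            model = self._train_base_tagger(documents)
            for doc in documents:
                outputs[doc.id] = [
                    beam_decode(model, ctx, cfg.beam, source=ME_LABELER)
                    for ctx in self._contexts(doc)
                ]
            return outputs
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(documents))
        folds = [sorted(order[i::k]) for i in range(k)]
        for fold in folds:
            held = set(fold)
            train_docs = [d for j, d in enumerate(documents) if j not in held]
            model = train_tagger(
                self._tagger_training_rows(train_docs),
                templates=cfg.templates,
                C=cfg.tagger_C,
                seed=cfg.seed,
            )
            for j in fold:
                doc = documents[j]
                outputs[doc.id] = [
                    beam_decode(model, ctx, cfg.beam, source=ME_LABELER)
                    for ctx in self._contexts(doc)
                ]
        return outputs

    def fit(self, documents: list[Document]) -> "HybridNER":
        cfg = self.config
        if cfg.use_tagger and ME_LABELER not in cfg.disabled:
            self.tagger = self._train_base_tagger(documents)
        if cfg.resolver in ("me", "ltr"):
            crossfit = (
                self.crossfit_tagger_outputs(documents)
                if self.tagger is not None
                else {}
            )
            per_doc_cs = {
                doc.id: self.candidate_sets(doc, crossfit.get(doc.id))
                for doc in documents
            }
            if cfg.resolver == "me":
                training = []
                for doc in documents:
                    for i, cs in enumerate(per_doc_cs[doc.id]):
                        training.append(
                            (doc.token_texts(i), cs, doc.gold_bio(i).tags)
                        )
                self._me_sources = tuple(
                    sorted({s for _, cs, _ in training for s in cs.sources})
                )
                self.me_resolver = train_me_resolver(
                    training,
                    templates=cfg.resolver_templates,
                    C=cfg.resolver_C,
                    seed=cfg.seed,
                )
            else:
                queries = []
                for doc in documents:
                    for i, cs in enumerate(per_doc_cs[doc.id]):
                        gold = doc.gold_bio(i).tags
                        for q in build_rank_lists(cs, gold):
                            feats = [
                                candidate_features(
                                    cs, doc.token_texts(i), q.segment, c.tags
                                )
                                for c in q.candidates
                            ]
                            queries.append((q, feats))
                self.ltr_model = train_ltr(
                    queries, C=cfg.resolver_C, seed=cfg.seed
                )
        return self

    # -- inference ----------------------------------------------------------

    def resolve(
        self, candidate_set: CandidateSet, tokens: list[str]
    ) -> LabelSequence:
        cfg = self.config
        if cfg.resolver == "priority":
            return resolve_priority(candidate_set, cfg.priority_order)
        if cfg.resolver == "me":
            if self.me_resolver is None:
                raise RuntimeError("ME resolver not trained; call fit() first")
            return resolve_me(
                self.me_resolver,
                candidate_set,
                tokens,
                cfg.beam,
                expected_sources=self._me_sources,
            )
        model = self.ltr_model if self.ltr_model is not None else LTRModel()
        return resolve_ltr(
            model,
            candidate_set,
            tokens,
            priority_order=cfg.priority_order,
        )

    def tag_document(self, document: Document) -> list[LabelSequence]:
        out = []
        for i, cs in enumerate(self.candidate_sets(document)):
            out.append(self.resolve(cs, document.token_texts(i)))
        return out

    def predict_mentions(self, document: Document) -> list[Mention]:
        mentions: list[Mention] = []
        for i, seq in enumerate(self.tag_document(document)):
            mentions.extend(
                bio_to_mentions(seq.tags, document.tokens[i], document.text)
            )
        return sorted(mentions)
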