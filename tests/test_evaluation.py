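"""Matching metrics, cross-validation, unique mentions, randomization test."""

import itertools

import numpy as np
import pytest

from phenorank.evaluation import (
    EvalCounts,
    RandomizationConfig,
    approx_randomization,
    compute_prf,
    cross_validate,
    f1_score,
    match_mentions,
    micro_average,
    unique_mention_eval,
)
from phenorank.model import Mention
from phenorank.pipeline import SystemConfig
from phenorank.synth import CorpusSpec, gen_corpus


def M(start, end, cls):
    return Mention(start, end, cls)


class TestMatchMentions:
    def test_partial_overlap_is_true_positive(self):
        # prediction "[median cleft lip]" vs gold "[cleft lip/palate]"
        gold = [M(7, 23, "PH")]
        pred = [M(0, 17, "PH")]
        c = match_mentions(gold, pred, "partial").cls("PH")
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_same_pair_exact_mode_fails(self):
        gold = [M(7, 23, "PH")]
        pred = [M(0, 17, "PH")]
        c = match_mentions(gold, pred, "exact").cls("PH")
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_identical_span_different_class(self):
        gold = [M(0, 5, "PH")]
        pred = [M(0, 5, "DS")]
        counts = match_mentions(gold, pred, "partial")
        assert (counts.cls("PH").fn, counts.cls("DS").fp) == (1, 1)
        assert counts.totals().tp == 0

    def test_one_to_one_pairing(self):
        # one long prediction cannot consume two gold mentions
        gold = [M(0, 5, "PH"), M(6, 10, "PH")]
        pred = [M(0, 10, "PH")]
        c = match_mentions(gold, pred, "partial").cls("PH")
        assert (c.tp, c.fp, c.fn) == (1, 0, 1)

    def test_partial_tp_never_below_exact_tp(self, rng):
        for _ in range(200):
            gold = [
                M(int(s), int(s) + int(rng.integers(1, 5)), "PH")
                for s in rng.choice(40, size=4, replace=False)
            ]
            pred = [
                M(int(s), int(s) + int(rng.integers(1, 5)), "PH")
                for s in rng.choice(40, size=4, replace=False)
            ]
            tp_partial = match_mentions(gold, pred, "partial").totals().tp
            tp_exact = match_mentions(gold, pred, "exact").totals().tp
            assert tp_partial >= tp_exact

    def test_greedy_never_overcounts_optimal_matching(self, rng):
        """Brute-force optimal bipartite matching oracle on <= 6 mentions."""

        from scipy.optimize import linear_sum_assignment

        def optimal_tp(gold, pred, mode):
            if not gold or not pred:
                return 0
            ok = np.zeros((len(pred), len(gold)))
            for p, pm in enumerate(pred):
                for g, gm in enumerate(gold):
                    if mode == "partial":
                        ok[p, g] = float(gm.overlaps(pm))
                    else:
                        ok[p, g] = float(
                            (gm.start, gm.end) == (pm.start, pm.end)
                        )
            rows, cols = linear_sum_assignment(-ok)
            return int(ok[rows, cols].sum())

        for _ in range(100):
            gold = [
                M(int(s), int(s) + int(rng.integers(1, 6)), "PH")
                for s in rng.choice(25, size=int(rng.integers(1, 4)), replace=False)
            ]
            pred = [
                M(int(s), int(s) + int(rng.integers(1, 6)), "PH")
                for s in rng.choice(25, size=int(rng.integers(1, 4)), replace=False)
            ]
            for mode in ("partial", "exact"):
                greedy_tp = match_mentions(gold, pred, mode).totals().tp
                assert greedy_tp <= optimal_tp(gold, pred, mode)


class TestPRF:
    def test_perfect_counts(self):
        counts = EvalCounts()
        counts.cls("PH").tp = 10
        prf = compute_prf(counts)["PH"]
        assert (prf.precision, prf.recall, prf.f1) == (1.0, 1.0, 1.0)

    def test_hand_computed_counts(self):
        counts = EvalCounts()
        c = counts.cls("PH")
        c.tp, c.fp, c.fn = 1, 1, 3
        prf = compute_prf(counts)["PH"]
        assert prf.precision == 0.5
        assert prf.recall == 0.25
        assert prf.f1 == pytest.approx(1 / 3)

    def test_zero_counts_give_zero(self):
        counts = EvalCounts()
        counts.cls("PH")
        prf = compute_prf(counts)["PH"]
        assert (prf.precision, prf.recall, prf.f1) == (0.0, 0.0, 0.0)

    def test_harmonic_mean_on_reported_scale(self):
        # P=74.3, R=76.4 -> F=75.3 on the x100 scale
        assert round(100 * f1_score(0.743, 0.764), 1) == 75.3


class TestMicroAverage:
    def test_single_class_equals_class_prf(self):
        counts = EvalCounts()
        c = counts.cls("PH")
        c.tp, c.fp, c.fn = 3, 1, 2
        assert micro_average(counts) == compute_prf(counts)["PH"]

    def test_two_class_hand_computation(self):
        counts = EvalCounts()
        counts.cls("A").tp = 1
        b = counts.cls("B")
        b.fp, b.fn = 1, 1
        assert micro_average(counts).f1 == pytest.approx(0.5)

    def test_all_zero(self):
        assert micro_average(EvalCounts()).f1 == 0.0


def small_corpus(seed=5, n_docs=6):
    spec = CorpusSpec(
        seed=seed,
        n_docs=n_docs,
        sentences_per_doc=3,
        nesting_prob=0.0,
        mention_rate={"PH": 0.8, "DS": 0.8},
        vocab_size={"PH": 25, "DS": 25},
    )
    return gen_corpus(spec)


def dict_only_config(corpus, **kw):
    return SystemConfig(
        lexicons=tuple(corpus.lexicons.values()), use_tagger=False, **kw
    )


class TestCrossValidate:
    def test_every_document_tested_exactly_once(self):
        c = small_corpus()
        frs, _ = cross_validate(c.documents, dict_only_config(c), k=2, seed=0)
        tested = [d for fr in frs for d in fr.test_doc_ids]
        assert sorted(tested) == sorted(d.id for d in c.documents)

    def test_pooled_counts_are_fold_sums(self):
        c = small_corpus()
        frs, pooled = cross_validate(c.documents, dict_only_config(c), k=2, seed=0)
        total = sum(fr.counts.totals().tp for fr in frs)
        assert pooled.totals().tp == total

    def test_same_seed_same_folds(self):
        c = small_corpus()
        frs1, _ = cross_validate(c.documents, dict_only_config(c), k=3, seed=7)
        frs2, _ = cross_validate(c.documents, dict_only_config(c), k=3, seed=7)
        assert [f.test_doc_ids for f in frs1] == [f.test_doc_ids for f in frs2]

    def test_corpus_smaller_than_k_rejected(self):
        c = small_corpus(n_docs=3)
        with pytest.raises(ValueError):
            cross_validate(c.documents, dict_only_config(c), k=10, seed=0)


class TestUniqueMentions:
    def _folds_with(self, train_surfaces, test_surfaces):
        from phenorank.evaluation import FoldResult

        text_pos = 0
        train_gold = []
        for s in train_surfaces:
            train_gold.append(Mention(text_pos, text_pos + len(s), "PH", s))
            text_pos += len(s) + 1
        test_gold = []
        for s in test_surfaces:
            test_gold.append(Mention(text_pos, text_pos + len(s), "PH", s))
            text_pos += len(s) + 1
        return [
            FoldResult(
                fold=0,
                train_doc_ids=["tr"],
                test_doc_ids=["te"],
                counts=EvalCounts(),
                sentence_outputs=[],
                train_gold=train_gold,
                test_doc_gold={"te": test_gold},
                test_doc_pred={"te": list(test_gold)},
            )
        ]

    def test_disjoint_train_test_rate_100(self):
        frs = self._folds_with(["aa", "bb"], ["cc", "dd"])
        _, rates, _ = unique_mention_eval(frs)
        assert rates["PH"] == 100.0

    def test_test_subset_of_train_rate_0(self):
        frs = self._folds_with(["aa", "bb"], ["aa", "bb"])
        _, rates, _ = unique_mention_eval(frs)
        assert rates["PH"] == 0.0

    def test_one_of_four_repeated_rate_75(self):
        frs = self._folds_with(["aa"], ["aa", "bb", "cc", "dd"])
        _, rates, _ = unique_mention_eval(frs)
        assert rates["PH"] == 75.0


class TestApproxRandomization:
    def _outputs(self, n=6, seed=0):
        rng = np.random.default_rng(seed)
        gold, a, b = [], [], []
        pos = 0
        for _ in range(n):
            g = [M(pos, pos + 4, "PH"), M(pos + 5, pos + 8, "DS")]
            gold.append(g)
            a.append([m for m in g if rng.random() < 0.9])
            b.append([m for m in g if rng.random() < 0.5])
            pos += 20
        return gold, a, b

    def test_identical_systems_p_one(self):
        gold, a, _ = self._outputs()
        report = approx_randomization(a, a, gold, RandomizationConfig(100, 0))
        assert report["delta"] == 0.0
        assert report["p"] == 1.0

    def test_swapping_systems_negates_delta(self):
        gold, a, b = self._outputs()
        cfg = RandomizationConfig(10, 0)
        d_ab = approx_randomization(a, b, gold, cfg)["delta"]
        d_ba = approx_randomization(b, a, gold, cfg)["delta"]
        assert d_ab == pytest.approx(-d_ba)

    def test_exhaustive_matches_enumeration_oracle(self):
        gold, a, b = self._outputs(n=6)
        report = approx_randomization(
            a, b, gold, RandomizationConfig(repetitions=1, seed=0, method="exhaustive")
        )
        assert report["repetitions"] == 64

        # independent oracle: enumerate all swap patterns with itertools
        def micro_f(outs):
            counts = EvalCounts()
            for g, p in zip(gold, outs):
                counts.add(match_mentions(g, p, "partial"))
            return micro_average(counts).f1

        delta = micro_f(a) - micro_f(b)
        hits = 0
        for mask in itertools.product([False, True], repeat=6):
            x = [b[i] if m else a[i] for i, m in enumerate(mask)]
            y = [a[i] if m else b[i] for i, m in enumerate(mask)]
            if micro_f(x) - micro_f(y) >= delta:
                hits += 1
        assert report["p"] == pytest.approx(hits / 64)

    def test_mismatched_sentence_sets_rejected(self):
        gold, a, b = self._outputs()
        with pytest.raises(ValueError):
            approx_randomization(a[:-1], b, gold, RandomizationConfig(10, 0))
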