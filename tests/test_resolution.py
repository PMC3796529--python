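"""Hypothesis resolution: ambiguity detection, priority merge, rank lists,
learn-to-rank and maximum-entropy re-labeling."""

import numpy as np

from phenorank.model import repair_bio, tag_class
from phenorank.resolution import (
    build_rank_lists,
    candidate_features,
    detect_ambiguity,
    resolve_ltr,
    resolve_me,
    resolve_priority,
    train_ltr,
    train_me_resolver,
    LTRModel,
)

from conftest import candidate_set


class TestDetectAmbiguity:
    def test_disjoint_proposals_are_unambiguous(self):
        # one labeler: PH on "X Y"; another: GG on "W Z"; no conflict
        cs = candidate_set(
            ("a", ["B-PH", "I-PH", "O", "O", "O"]),
            ("b", ["O", "O", "O", "B-GG", "I-GG"]),
        )
        report = detect_ambiguity(cs)
        assert report.ambiguous == [False] * 5
        assert report.segments == []
        # the agreed output is the union of the proposals
        assert resolve_priority(cs).tags == (
            "B-PH", "I-PH", "O", "B-GG", "I-GG",
        )

    def test_multiple_classes_on_one_token_is_ambiguous(self):
        cs = candidate_set(
            ("a", ["B-PH"]),
            ("b", ["B-GG"]),
            ("c", ["O"]),
            ("d", ["B-AN"]),
        )
        report = detect_ambiguity(cs)
        assert report.ambiguous == [True]
        assert report.segments == [(0, 1)]

    def test_full_agreement_empty_report(self):
        cs = candidate_set(
            ("a", ["B-PH", "I-PH"]), ("b", ["B-PH", "I-PH"])
        )
        report = detect_ambiguity(cs)
        assert report.ambiguous == [False, False]
        assert report.segments == []

    def test_segment_extends_to_participating_span_boundaries(self):
        cs = candidate_set(
            ("a", ["O", "B-PH", "I-PH", "I-PH", "O"]),
            ("b", ["O", "O", "O", "B-DS", "O"]),
        )
        report = detect_ambiguity(cs)
        assert report.ambiguous == [False, False, False, True, False]
        assert report.segments == [(1, 4)]


class TestResolvePriority:
    def test_boundary_conflict_merges_to_highest_priority(self):
        # [AB]_GG + [BC]_PH -> [ABC]_PH
        cs = candidate_set(
            ("gg", ["B-GG", "I-GG", "O"]),
            ("ph", ["O", "B-PH", "I-PH"]),
        )
        assert resolve_priority(cs).tags == ("B-PH", "I-PH", "I-PH")

    def test_embedded_gene_yields_containing_phenotype(self):
        # [high [IgE]_GG levels]_PH -> the containing PH span only
        cs = candidate_set(
            ("ph", ["B-PH", "I-PH", "I-PH"]),
            ("gg", ["O", "B-GG", "O"]),
        )
        assert resolve_priority(cs).tags == ("B-PH", "I-PH", "I-PH")

    def test_single_labeler_passes_through(self):
        tags = ("O", "B-DS", "I-DS", "O")
        cs = candidate_set(("only", list(tags)))
        assert resolve_priority(cs).tags == tags

    def test_disease_outranks_phenotype(self):
        cs = candidate_set(("a", ["B-PH", "I-PH"]), ("b", ["B-DS", "I-DS"]))
        assert resolve_priority(cs).tags == ("B-DS", "I-DS")

    def test_phenotype_outranks_gene(self):
        cs = candidate_set(("a", ["B-PH"]), ("b", ["B-GG"]))
        assert resolve_priority(cs).tags == ("B-PH",)

    def test_entity_never_demoted_to_o_and_idempotent(self, rng):
        classes = ["PH", "GG", "DS", "OR", "AN", "CD"]
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            hyps = []
            for h in range(int(rng.integers(1, 5))):
                tags = []
                for _ in range(n):
                    r = rng.random()
                    if r < 0.5:
                        tags.append("O")
                    else:
                        cls = classes[int(rng.integers(0, 6))]
                        tags.append(("B-" if r < 0.75 else "I-") + cls)
                hyps.append((f"h{h}", repair_bio(tags)))
            cs = candidate_set(*hyps)
            out = resolve_priority(cs)
            # no proposed entity token is demoted to O
            for i in range(n):
                proposed = any(
                    tag_class(t[i]) is not None for _, t in
                    ((s, h) for s, h in hyps)
                )
                if proposed:
                    assert out.tags[i] != "O"
            # idempotence: feeding the output back returns it unchanged
            again = resolve_priority(candidate_set(("out", list(out.tags))))
            assert again.tags == out.tags


class TestRankLists:
    def test_three_rule_tiers(self):
        # gold PH over tokens 0-2; candidates: exact PH, overlapping DS, all-O
        cs = candidate_set(
            ("exact", ["B-PH", "I-PH", "I-PH"]),
            ("overlap", ["O", "B-DS", "I-DS"]),
            ("none", ["O", "O", "O"]),
        )
        queries = build_rank_lists(cs, ("B-PH", "I-PH", "I-PH"))
        assert len(queries) == 1
        by_source = {c.source: c for c in queries[0].candidates}
        assert by_source["exact"].tier == 1 and by_source["exact"].rank == 1
        assert by_source["overlap"].tier == 2 and by_source["overlap"].rank == 2
        assert by_source["none"].tier == 3 and by_source["none"].rank == 3

    def test_leftmost_match_ranks_higher_within_tier(self):
        # two partial-overlap candidates; the left-starting one ranks higher
        # even though its source name sorts later
        cs = candidate_set(
            ("zz_left", ["B-PH", "I-PH", "O"]),
            ("aa_right", ["O", "B-DS", "I-DS"]),
        )
        gold = ("B-PH", "I-PH", "I-PH")
        (query,) = build_rank_lists(cs, gold)
        ranked = sorted(query.candidates, key=lambda c: c.rank)
        assert [c.tier for c in ranked] == [2, 2]
        assert ranked[0].source == "zz_left"

    def test_identical_candidates_deduplicate(self):
        cs = candidate_set(
            ("a", ["B-PH"]), ("b", ["B-PH"]), ("c", ["B-DS"])
        )
        (query,) = build_rank_lists(cs, ("B-PH",))
        assert len(query.candidates) == 2  # a/b collapse to one candidate
        assert query.candidates[0].rank == 1


def _make_ordering_queries(seed=0, n_queries=40):
    """Separable rank lists: candidates carry a feature that encodes their
    tier, so a linear ranker can order them perfectly."""
    rng = np.random.default_rng(seed)
    from phenorank.resolution import RankedCandidate, RankQuery

    queries = []
    for q in range(n_queries):
        qid = f"q{q}"
        query = RankQuery(query_id=qid, segment=(0, 2))
        feats = []
        order = rng.permutation(3)
        for pos, tier in enumerate(order):
            query.candidates.append(
                RankedCandidate(
                    query_id=qid, source=f"s{pos}", tags=("O", "O"),
                    tier=int(tier) + 1, rank=pos + 1,
                )
            )
            feats.append({f"grade{tier}": 1.0, f"noise{pos}": rng.random()})
        queries.append((query, feats))
    return queries


class TestLearnToRank:
    def test_separable_rank_lists_zero_pairwise_violations(self):
        queries = _make_ordering_queries()
        model = train_ltr(queries, seed=0)
        assert model.trained
        violations = 0
        for query, feats in queries:
            scores = [model.score(f) for f in feats]
            for i, a in enumerate(query.candidates):
                for j, b in enumerate(query.candidates):
                    if a.tier < b.tier and scores[i] <= scores[j]:
                        violations += 1
        assert violations == 0

    def test_single_candidate_segment_passes_through(self):
        cs = candidate_set(
            ("a", ["B-PH", "B-DS"]), ("b", ["B-PH", "B-DS"])
        )
        # tokens 0/1 unambiguous? token1: DS from both; token0 PH from both;
        # no conflict -> untrained model just returns the union
        out = resolve_ltr(LTRModel(), cs, ["asthma", "phenotypes"])
        assert out.tags == ("B-PH", "B-DS")

    def test_context_dependent_phenotype_choice(self):
        """On 'asthma and atopy phenotypes'-like conflicts the trained
        ranker picks PH from context where the priority list picks DS."""
        train_sents = []
        rng = np.random.default_rng(0)
        for k in range(60):
            ph_context = k % 2 == 0
            ctx_word = "phenotypes" if ph_context else "patients"
            gold_cls = "PH" if ph_context else "DS"
            tokens = ["w%d" % rng.integers(0, 30), "asthma", ctx_word]
            cs = candidate_set(
                ("dict_PH", ["O", "B-PH", "O"]),
                ("dict_DS", ["O", "B-DS", "O"]),
            )
            gold = ("O", f"B-{gold_cls}", "O")
            train_sents.append((tokens, cs, gold))
        queries = []
        for tokens, cs, gold in train_sents:
            for q in build_rank_lists(cs, gold):
                feats = [
                    candidate_features(cs, tokens, q.segment, c.tags)
                    for c in q.candidates
                ]
                queries.append((q, feats))
        model = train_ltr(queries, seed=0)
        cs = candidate_set(
            ("dict_PH", ["O", "B-PH", "O"]),
            ("dict_DS", ["O", "B-DS", "O"]),
        )
        tokens = ["w99", "asthma", "phenotypes"]
        assert resolve_priority(cs).tags[1] == "B-DS"  # DS outranks PH
        assert resolve_ltr(model, cs, tokens).tags[1] == "B-PH"
        tokens_ds = ["w98", "asthma", "patients"]
        assert resolve_ltr(model, cs, tokens_ds).tags[1] == "B-DS"


def _noiseless_training(n=40, seed=0):
    """Sentences whose labeler streams all agree with gold."""
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        length = int(rng.integers(3, 8))
        tokens, gold = [], []
        for _ in range(length):
            if rng.random() < 0.35:
                cls = ("PH", "DS", "GG")[int(rng.integers(0, 3))]
                tokens.append(f"{cls.lower()}{int(rng.integers(0, 12))}")
                gold.append(f"B-{cls}")
            else:
                tokens.append(f"w{int(rng.integers(0, 12))}")
                gold.append("O")
        cs = candidate_set(("s1", list(gold)), ("s2", list(gold)))
        rows.append((tokens, cs, tuple(gold)))
    return rows


class TestMEResolver:
    def test_noiseless_streams_reproduce_gold(self):
        rows = _noiseless_training()
        model = train_me_resolver(rows, seed=0)
        correct = total = 0
        for tokens, cs, gold in rows:
            out = resolve_me(model, cs, tokens)
            correct += sum(a == b for a, b in zip(out.tags, gold))
            total += len(gold)
        assert correct / total >= 0.99

    def test_systematically_wrong_labeler_downweighted(self):
        rng = np.random.default_rng(1)
        rows = []
        for _ in range(60):
            length = int(rng.integers(3, 8))
            tokens, gold, wrong = [], [], []
            for _ in range(length):
                if rng.random() < 0.35:
                    tokens.append(f"ph{int(rng.integers(0, 12))}")
                    gold.append("B-PH")
                    wrong.append("B-DS")  # systematic PH->DS confusion
                else:
                    tokens.append(f"w{int(rng.integers(0, 12))}")
                    gold.append("O")
                    wrong.append("O")
            cs = candidate_set(
                ("good", list(gold)), ("bad", list(wrong))
            )
            rows.append((tokens, cs, tuple(gold)))
        model = train_me_resolver(rows, seed=0)
        res_correct = bad_correct = total = 0
        for tokens, cs, gold in rows:
            out = resolve_me(model, cs, tokens)
            res_correct += sum(a == b for a, b in zip(out.tags, gold))
            bad_correct += sum(
                a == b for a, b in zip(cs.hypotheses["bad"].tags, gold)
            )
            total += len(gold)
        assert res_correct / total > bad_correct / total

    def test_empty_streams_reduce_to_word_tagger(self):
        rows = []
        for tokens, cs, gold in _noiseless_training():
            empty = candidate_set()
            rows.append((tokens, empty, gold))
        model = train_me_resolver(rows, seed=0)
        correct = total = 0
        for tokens, cs, gold in rows:
            out = resolve_me(model, cs, tokens)
            correct += sum(a == b for a, b in zip(out.tags, gold))
            total += len(gold)
        assert correct / total >= 0.95
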