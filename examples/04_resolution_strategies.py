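"""Compare the three hypothesis-resolution strategies on one conflict.

Two dictionary labelers disagree on "asthma": the DS dictionary calls it
a disease, the PH dictionary (here via a phenotype lexicon that lists
"asthma phenotypes") proposes a phenotype span.  The priority list always
prefers DS; a trained learn-to-rank model uses the context to decide.
"""

import numpy as np

from phenorank import resolve_ltr, resolve_priority, train_ltr
from phenorank.model import CandidateSet, LabelSequence
from phenorank.resolution import build_rank_lists, candidate_features


def conflict(tokens):
    return CandidateSet(
        sentence_index=0,
        hypotheses={
            "dict_PH": LabelSequence("dict_PH", ("O", "B-PH", "O")),
            "dict_DS": LabelSequence("dict_DS", ("O", "B-DS", "O")),
        },
    )


# training sentences: "... asthma phenotypes" is annotated PH,
# "... asthma patients" is annotated DS
rng = np.random.default_rng(0)
queries = []
for k in range(60):
    ph_context = k % 2 == 0
    tokens = [f"w{rng.integers(0, 30)}", "asthma",
              "phenotypes" if ph_context else "patients"]
    cs = conflict(tokens)
    gold = ("O", "B-PH" if ph_context else "B-DS", "O")
    for q in build_rank_lists(cs, gold):
        feats = [candidate_features(cs, tokens, q.segment, c.tags)
                 for c in q.candidates]
        queries.append((q, feats))
ltr = train_ltr(queries, seed=0)

for tokens in (["the", "asthma", "phenotypes"], ["the", "asthma", "patients"]):
    cs = conflict(tokens)
    print(" ".join(tokens))
    print("  priority list :", resolve_priority(cs).tags[1])
    print("  learn-to-rank :", resolve_ltr(ltr, cs, tokens).tags[1])
# The priority list picks DS in both contexts (DS outranks PH); the
# ranker recovers PH before "phenotypes" and DS before "patients".
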