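import numpy as np
import pytest

from phenorank.corpus import segment_and_tokenize
from phenorank.model import CandidateSet, Document, LabelSequence, Mention


def make_document(text: str, mentions=(), doc_id: str = "doc") -> Document:
    """Build a validated Document from raw text and (start, end, class) triples."""
    sents, toks = segment_and_tokenize(text)
    ms = [Mention(s, e, c, text[s:e]) for s, e, c in mentions]
    doc = Document(
        id=doc_id, text=text, sentences=sents, tokens=toks, gold_mentions=sorted(ms)
    )
    doc.validate()
    return doc


def candidate_set(*hypotheses: tuple[str, list[str]]) -> CandidateSet:
    """CandidateSet from (source, tags) pairs."""
    return CandidateSet(
        sentence_index=0,
        hypotheses={
            src: LabelSequence(src, tuple(tags)) for src, tags in hypotheses
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
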