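# Methods

This note documents the models and procedures implemented in `phenorank`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic corpora do and do not establish.

## Task and data model

The task is span-level named entity recognition over six classes —
phenotype (PH), gene/gene product (GG), disease (DS), organism (OR),
anatomy (AN), chemical/drug (CD) — in abstracts annotated in BRAT
standoff format. Character offsets are 0-based and half-open throughout.
Per sentence, mentions are encoded with the BIO scheme. Two facts shape
the core model:

- **Nesting.** A gene mention may sit inside a phenotype mention
  (*high [IgE] levels* as a PH). The mention layer keeps both; BIO
  flattens to the outermost span. Any other overlap between gold
  mentions is rejected.
- **Repair.** Labelers and decoders can emit ill-formed tag sequences; a
  dangling `I-X` (after `O`, after a different class, or sentence-
  initially) is rewritten to `B-X`. This is the recall-preserving
  convention: it keeps the proposed tokens as a mention instead of
  discarding them. Every sequence leaving any component is repaired.

Sentence segmentation and tokenization are rule-based and deterministic:
whitespace splitting with punctuation detached, hyphen/apostrophe-joined
tokens kept whole, and sentence breaks after `.!?` only when followed by
whitespace and an upper-case letter, digit or opening bracket. The
deliberate consequence is that *E. coli*-style abbreviations followed by
lower case do not split. Abbreviation expansion (off by default) detects
parenthesis-adjacent definitions by right-to-left character alignment of
the short form against the preceding words and replaces later standalone
occurrences with the long form; a replacement that would split a gold
mention boundary is skipped with a warning, and all mention offsets are
remapped across the rewrite.

## Labelers

**Dictionary labelers.** One per entity class. Entries (terms plus
synonyms, from plain-text, TSV or OBO inputs) are lower-cased and
plural-normalized at load; matching joins plural-normalized tokens with
single spaces and scans left to right taking the longest entry at each
position (leftmost-longest, standard gazetteer semantics; the tie rule
is needed because the underlying description — "longest string
matching, normalising for plurals" — does not fix it). Token-level
matching avoids substring false hits. The plural rule is a string rule
(strip `ies`→`y`; `es` after s/x/z/ch/sh; else a final `s` when the
token is long enough and does not end in `ss`); outputs for irregular
forms are whatever the rule yields, and tests freeze the rule's output,
not a linguistic claim.

**Rule labeler.** Composes post-composed phenotype candidates: head
terms from other-class lexicons (default AN, GG, DS) are matched by the
dictionary machinery, then extended over contiguous quality-modifier
tokens on both sides; any span extended beyond the bare head is
relabeled PH. Unextended heads are emitted only if configured
(`emit_heads`), default off — the labeler's job is phenotype
composition, and the per-class dictionaries already cover bare heads.
The two-sided extension is a reconstruction: one-sided (left-only)
extension cannot produce *high IgE levels* with the trailing head noun,
so quality nouns like *levels* live in the modifier list.

**Statistical tagger.** A per-token multinomial logistic-regression
(maximum-entropy) classifier over sparse indicator features: focus and
context words in a ±2 window; prefix (2/3 chars) and collapsed
character-shape features of windowed words; any auxiliary per-token tag
stream (part of speech, species tags, an external tagger's output),
windowed the same way; and the previous two assigned tags. Training uses
gold previous tags; L2 regularization with C = 10 by default
(`lbfgs`, deterministic); a single-label degenerate corpus is handled by
a constant model. Expected labels missing from the training data are
reported with a warning.

**Decoding.** Because previous-tag features couple decisions, decoding
keeps the K best-scoring tag prefixes (sum of per-position
log-probabilities); K = 3 by default, linear complexity in sentence
length × labels × K. Ties are broken toward the lexicographically
smaller tag sequence at both pruning and final selection, which makes
saturated-K beam search agree *exactly* (including float equality, since
both accumulate the same terms in the same order) with the exhaustive
enumeration decoder used as a test oracle. The exhaustive decoder
refuses search spaces beyond 10⁶ sequences.

## Hypothesis resolution

A token is **ambiguous** when at least two distinct entity classes are
proposed for it. Entity-versus-O and same-class boundary differences are
not conflicts: the union rule settles them (this follows the worked
unambiguous/ambiguous example in the architecture the package
implements, where disjoint PH and GG proposals over otherwise-O streams
are explicitly the unambiguous case). Ambiguous segments are maximal
ambiguous runs extended, to fixpoint, to the boundaries of every
hypothesis span touching them — so no labeler's span is ever split by a
segment boundary.

**Priority list.** All proposed entity spans are kept (O has least
priority); spans sharing tokens merge, to fixpoint, into their union
labeled with the highest-priority participating class. Default order
DS > PH > GG > AN > CD > OR > O; only fragments of this order have
direct ontological motivation (DS over PH, PH over GG, DS over OR, GG
over OR), the rest is a configuration default and fully configurable.
The unified merge rule subsumes the embedding case (embedded GG inside
PH keeps the containing PH) and the boundary-conflict case
([AB]\_GG + [BC]\_PH → [ABC]\_PH), and it is idempotent.

**Maximum-entropy re-labeling.** A second MaxEnt+beam model re-labels
every token, with features = current word, context words, and every
labeler's proposed tag (windowed). No morphological features: the
resolution feature set is words plus label streams by design, which
also keeps the resolver honest on synthetic corpora whose token
orthography encodes the class. No ambiguity screening. When a learned
labeler feeds the resolver, its outputs on the resolver's own training
documents are **cross-fitted** (predicted by models trained on held-out
folds within the training partition, 3 folds by default): training on
resubstituted outputs would let the resolver trust the tagger more than
it deserves. A hypothesis stream expected at inference but missing is
substituted with all-O plus a warning.

**Learn-to-rank.** Unambiguous content is fixed first. Per ambiguous
segment, each labeler's (locally repaired) tag assignment is a
candidate; identical assignments deduplicate. Training queries rank
candidates by three rules — (1) exact span+class agreement with the
annotation, (2) partial overlap in tag assignment, (3) no overlap — with
candidates matching further left ranked higher within a tier and source
name as the residual tie-break. Rule 2 is class-agnostic span overlap
(forced by the reference example in which a GG candidate against PH gold
takes the middle rank). The learner is a pairwise large-margin linear
ranker: for every in-query pair with tier(a) < tier(b) it receives the
constraint score(a) > score(b), fit as a linear SVM on feature
differences (C = 1, deterministic primal solver). Pairs are generated
from tiers, not the within-tier positional order, since left-position is
bookkeeping rather than a feature-learnable property. Candidate features
conjoin the candidate's tags with the words and with every labeler's
tags over the segment, plus the candidate's leading class conjoined with
the words around the segment — the signal that lets context decide
PH-versus-DS conflicts. At inference the top-scoring candidate's tags
are emitted; a single-candidate segment passes through; an untrained
model falls back to the priority list.

## Evaluation

**Matching.** Greedy left-to-right one-to-one matching with per-class
pools: a prediction is TP iff it pairs with an unmatched same-class gold
mention whose span overlaps it (partial mode) or equals it (exact mode).
One-to-one pairing prevents one long prediction from matching several
gold mentions; greedy is compared against an optimal-assignment oracle
in tests and never overcounts. P = TP/(TP+FP), R = TP/(TP+FN), F1 the
harmonic mean, 0 on zero denominators; micro-averages pool counts over
classes first. Partial-mode TP is monotonically ≥ exact-mode TP.

**Cross-validation.** The fold unit is the document (abstract), not the
sentence — sentences of one abstract share vocabulary and would leak.
Folds are a seeded shuffle split into k near-equal parts; counts are
pooled over folds before computing PRF.

**Unique mentions.** A test gold mention is unique in its fold when its
normalized (surface, class) never occurs as gold in that fold's training
part. Unique-only PRF restricts gold to unique mentions and drops
predictions that match a *seen* gold mention of the same class (those
are credited to memorization); the unique rate is unique/total gold
×100. The restriction rule for predictions is this package's choice;
the quantity is otherwise underdetermined.

**Approximate randomization.** The observed statistic is the micro-F
difference δ = F_A − F_B over pooled per-sentence outputs. Each
repetition independently swaps each sentence's two system outputs
between two pseudo-systems (paired sentence-level shuffle) and recomputes
the pseudo-δ; p = #(pseudo-δ ≥ δ)/R, R = 1000 by default, seeded. An
exhaustive variant enumerates all 2ⁿ swap patterns for n ≤ 20 and is the
oracle in tests. Under exchangeable (null) systems the p-value is
approximately uniform; the suite checks its CDF at deciles within ±0.1.
Per-sentence TP/FP/FN are precomputed once, so repetitions are cheap.

## Synthetic corpora

The generator emits BRAT `.txt`/`.ann` pairs (so fixtures exercise the
real readers) whose structure emulates an annotated auto-immune abstract
collection: six classes at reference per-sentence densities derived from
a 122-abstract, ~4,000-mention profile (PH 472, OR 764, DS 875, GG 1611,
AN 188, CD 48), mention lengths 1 + Poisson with class means
3.0/1.8/1.9/1.7/2.2/1.4, single-token genes nested inside phenotype
mentions with configurable probability (default 0.1; the reference
corpus documents the phenomenon but not a rate), per-class vocabularies
at the reference unique-entity counts, and per-class lexicons covering a
configurable fraction of the gold vocabulary. Sentences are template
token streams, not natural language — mentions separated by filler
tokens, each sentence opened by a capitalized filler and closed by a
period so the real tokenizer reproduces the generation exactly.

Two token-orthography regimes: **class-prefixed** tokens (`ph12`) make
every class learnable from shape alone — used for plumbing and invariant
tests where exact expected outputs matter; **shared-pool** tokens
(`x123`, `shared_token_pool=True`) carry no class signal, so class
identity must come from term identity (dictionaries) and context — the
harder regime used for the headline experiments, where dictionary
coverage and resolution strategy actually matter. Controlled labeler
noise (per-labeler drop rate, one-token boundary jitter, class-confusion
matrix, visible-class restriction) corrupts gold mentions into synthetic
hypothesis streams for resolution experiments.

What passing tests on these corpora show: the pipeline's mechanics,
determinism, the structural invariants, and the *qualitative* behavior
of the resolution strategies under controlled disagreement. What they do
not show: performance on real biomedical prose, where tokenization,
spelling variation, discontinuous and coordinated mentions, and genuine
ontology gaps dominate.

## Numerical and degenerate-input choices

- Seeds are explicit everywhere randomness exists (corpus generation,
  noise, fold shuffling, randomization test, learners).
- Regularization defaults: tagger C = 10, resolvers C = 1 (ME resolver
  runs at C = 100 in the headline experiments where streams are trusted);
  exposed in `SystemConfig`.
- Beam/exhaustive tie rule: lexicographically smaller tag sequence.
- Rank-list residual ties: source name.
- LTR score ties at inference: lexicographically smaller tags, then
  source.
- Empty lexicons are configuration errors; empty hypothesis sets resolve
  to all-O; zero-token sentences decode to empty sequences; single-label
  training data yields a constant model.
- On a noiseless, full-coverage corpus with the deterministic labelers,
  the priority-list and LTR resolvers reproduce gold exactly (a
  structural property of the union rule and agreed-segment passthrough).
  The ME re-labeler approaches but does not structurally guarantee exact
  reproduction: with perfectly agreeing training streams the learner
  splits weight across collinear stream features, and an unseen word at
  test can tip a rare-class token to O. Its contract is therefore token
  accuracy ≥ 0.99 in that setting (observed micro-F 0.98–1.0), which is
  also consistent with this strategy placing last in the resolver
  comparison.

## Problem sizes

The test suite and the acceptance script run scaled-down experiments
chosen as the smallest sizes at which the measured properties are stable
across seeds: resolver-ordering runs use 30 documents × 4 sentences over
10 seeds; the end-to-end invariant uses 16 balanced documents; the
acceptance experiment uses 40 documents × 6 sentences at the reference
densities with 5-fold cross-validation, 90% dictionary coverage and
R = 1000 randomization repetitions.

## Known limitations

- Discontinuous and coordinated mentions are out of scope; cross-
  sentence mentions are rejected.
- The priority resolver's union rule keeps every labeler's false
  positives; under heavy cross-class lexical collision its precision
  degrades sharply (visible in the acceptance numbers), which is the
  behavior the learned resolvers exist to fix.
- The rule labeler is a modifier-composition reconstruction, not a
  semantic grounding system; its stages are deliberately simple and the
  labeler interface is pluggable.
- Ontology acquisition is a user action: the lexicon loader accepts any
  term list (plain text, TSV, OBO); no resource is downloaded.
- Mapping recognized candidates to ontology concepts (grounding /
  post-composition) is future work by design.
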