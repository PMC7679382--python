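# Methods

`pathkey` implements a supervised keyword-extraction pipeline for free-text
pathology reports. A report is split into per-specimen *statements*, each
statement is normalized and tokenized to subwords, a tagger scores every
token over the four classes {SPE, PRO, PAT, O} (specimen, procedure,
pathology, otherwise), token scores are aggregated back to word-level class
probabilities, and the words of each keyword class are joined into that
type's keyword string. Extracted keywords can additionally be scored
against a standard-vocabulary term list with Wu–Palmer taxonomy similarity.

## Text model and preprocessing

A *statement* is one paragraph of a report, delimited by runs of two or
more line breaks; trailing free-text note blocks are statements without
keywords. Normalization case-folds and treats every character outside
`[a-z0-9]` as a word boundary; digits are retained because keywords may
contain stage codes (`t2n0m0`). This is the strictest reading of
"special characters removed" that keeps word boundaries recoverable.

Subword tokenization is greedy longest-match-first over a WordPiece-style
vocabulary (continuation pieces prefixed `##`); a word with no valid
segmentation becomes the unknown token. When no vocabulary file is
supplied, a frequency-based trainer builds one from the corpus: all single
characters (both piece forms) are seeded so every word is tokenizable, then
the budget (default 2,000 pieces) is spent on whole words by frequency and
on frequent prefixes/suffixes. This count-based construction is not a
likelihood-driven trainer, but it emits the standard file dialect and the
same greedy segmentation behaviour, which is what the rest of the pipeline
depends on.

Gold labeling tags **every** occurrence of each gold keyword phrase
(contiguous within the phrase); remaining words are O, and each subword
token inherits its word's tag. Cross-class conflicts on one word are
resolved with the fixed precedence SPE > PRO > PAT and logged. Statements
are truncated at 512 tokens (the encoder-family limit).

## Taggers

All taggers emit pre-softmax scores `p_ij^l` for token `j` of word `i`,
class order fixed as (SPE, PRO, PAT, O) = (0, 1, 2, 3):

* **Naive Bayes** (token identity only): score =
  `log[(count(t,l)+α)/(count(l)+αV)] + log prior(l)` with Laplace `α = 1`
  and `V` distinct training tokens. Priors are smoothed the same way so a
  class absent from training keeps a finite score. Bayes emits
  log-probabilities in the `p_ij^l` slot so one decoding path serves every
  model.
* **Recurrent tagger**: embedding (32) → tanh recurrent layer (64) →
  linear head. **Convolutional tagger**: embedding → two width-3 ReLU
  convolution layers (64 channels) → linear head; max pooling is omitted
  because tagging needs one output per token. **Transformer encoder**: a
  tiny from-scratch pre-LN encoder (2 layers, 128 hidden, 2 heads, learned
  positions); the full-scale preset (12 layers, 768 hidden, 12 heads,
  learning rate 2e-5, batch 16) is retained as a named configuration.
  All three are implemented in numpy with hand-written backpropagation,
  verified against central finite differences in the test suite.
* Optimization: Adam, cross-entropy per token, batch 16, default learning
  rate 1e-3 for the small from-scratch taggers (2e-5 is a fine-tuning rate
  for pre-trained weights and is kept with the full-scale preset). Training
  is deterministic given the seed.

## Next-statement pre-training (NSP)

The pair corpus is built constructively: exactly one third of the pairs
(`(n+1)//3`) are adjacent statements of one report (*IsNext*), the rest
random non-adjacent selections (*NotNext*). Each segment is encoded by the
tagger (masked mean of token states); a logistic head over
`[h_a, h_b, h_a·h_b, |h_a−h_b|]` classifies the pair. Training stops when
the running accuracy over the last 50 mini-batches reaches the threshold
(default 99%) or at `max_steps`; the head is discarded and the encoder
keeps its trained weights.

The `update` switch selects which encoder parameters the pretext task
trains. With `update="encoder"` (everything), we observed that the
recurrent dynamics specialize to pooled pair comparison and downstream
tagging fine-tunes *slower* than from random initialization. With
`update="embedding"`, pre-training shapes only the word representations and
preserves a modest acceleration early in fine-tuning. On template corpora
token identity is already fully informative for the tagging task and
learnable from the labeled set alone, so representation transfer is
inherently limited; the benefit experiment therefore measures epochs to a
mid-curve F1 threshold (0.7) on a 300-statement labeled set, where the
early-training effect is visible, with a 3-seed majority. This is the
package's own operating point for demonstrating the phenomenon at desk
scale; it does not imply a comparable effect size on natural clinical text.

## Decoding

Word-level class probabilities follow
`w_i^l = Σ_j exp(p_ij^l) / Σ_j Σ_l' exp(p_ij^l')` over the word's tokens;
the implementation subtracts the per-word maximum score before
exponentiation (algebraically exact, overflow-safe, agreement with the
naive evaluation to 1e-12 in tests). The word class is `argmax_l w_i^l`
with ties broken by the fixed class order (first maximum wins). Per type,
selected words are joined in text order; immediately repeated identical
words are collapsed once, which undoes the duplication that all-occurrence
labeling can introduce without corrupting legitimate repetition. Non-
adjacent same-class words are joined into one string because evaluation
compares one keyword string per type per statement.

## Evaluation

Precision/recall/F1 are word-level and micro-averaged across statements
(the taggers classify words; token-level would overweight long words).
Undefined ratios (empty denominator) are reported as 0 with an explicit
flag. Exact matching is the fraction of statements whose assembled string
equals the normalized gold string character for character — stricter than
word-level P/R, and the pipeline reproduces that ordering on synthetic
corpora. Cross-entropy is the mean token loss, computed with log-sum-exp.
The ablation harness retrains from scratch on seeded subsamples of
configurable sizes (default grid 100/300/500/1000/3000) and records
per-epoch exact matching per type on a fixed test split.

## Vocabulary similarity

The taxonomy is a rooted hierarchy (optionally a DAG) loaded from a TSV
edge list plus a word→sense map. Depth counts nodes from the root with
depth(root) = 1 — the convention of the dominant WordNet implementations —
so identical single-sense words score exactly 1. Word similarity is the
maximum over sense pairs of `2·depth(lcs)/(depth(a)+depth(b))`; a word
with no senses scores 0. Keyword-vs-term similarity computes all word
pairs and averages the strictly positive values (zeros are excluded; if
all pairs are zero the score is 0); a keyword's vocabulary score is the
maximum over terms, first term winning ties. Note that under all-pairs
averaging a multi-word phrase matched against itself scores slightly below
1 (cross pairs enter the mean); exact self-similarity holds for
single-word keywords. The combined specimen+pathology set pairs each
statement's specimen and pathology strings as space-joined composites
before deduplication. The score distribution uses 20 right-closed bins on
[0, 1] with the zero-score count reported separately. Part-of-speech
filtering is supported by loading one taxonomy per part of speech
(noun-only by default); the real MeSH/NAACCR vocabularies are pluggable
inputs, never bundled.

## Synthetic corpus

The generator emulates the structural features of the study data: 1–3
statements per report separated by ≥2 line breaks, an optional trailing
note block (probability 0.3), keywords present but not necessarily
adjacent in the text, and occasional typos (rate 0.05, single character
substitution/deletion, filler words only so gold stays well defined — a
flag allows keyword typos for robustness experiments). Default lexicon
sizes 50/20/60 (specimen/procedure/pathology) echo the relative unique-
keyword counts of the study dataset, where procedure has far fewer
distinct values. The three keyword lexicons are pairwise word-disjoint and
disjoint from the filler lexicon, making the corpus *separable*: a word's
class is unambiguous, so a perfect tagger can recover every gold keyword
— which is what makes end-to-end recovery a meaningful oracle test.

All statements of one report share the specimen and procedure phrase (a
multi-part case of one organ and procedure, as in real multi-part
reports), and multi-part reports carry "Part k." prefixes. Report
membership is therefore statistically identifiable, which makes
next-statement prediction learnable by construction.

What the generator does **not** model: institutional report formats,
narrative grammar, Korean-language content, clinically plausible
keyword co-occurrence, abbreviation ambiguity, or vocabulary drift.
Passing tests on separable synthetic corpora demonstrate the correctness
of the pipeline's mechanics, not expected accuracy on real reports.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale as the package's
standard conditions: corpora of 300–1,500 reports, subword vocabulary of
2,000 pieces, NSP corpora of 2,000–5,000 pairs, ablation sizes 100 vs
3,000, and 3-seed majorities for stochastic comparisons. Every source of
randomness flows from one seed through named `SeedSequence` substreams
(corpus, split, initialization, typos, NSP), so full runs are reproducible
from the manifest written by the pipeline.

## Known limitations

* The Bayes tagger uses token identity only (no context features), so it
  cannot use positional cues; on natural text its exact matching degrades
  far more than its word-level P/R.
* The WordPiece trainer is count-based, not likelihood-driven; segmentations
  of rare words can differ from those of a standard trainer.
* NSP-only pre-training (no masked-LM, which is out of scope) yields only
  a small, early-fine-tuning benefit under separable synthetic conditions;
  see above.
* Span-level (BIO) decoding and confidence calibration are out of scope;
  multiple disjoint same-class spans are merged into one keyword string.
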