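# Methods

## The measurement model

`coherograph` quantifies the semantic coherence of interview speech with
two cosine-similarity metrics computed over sentence embeddings. For a
section with sentence vectors S = (s₁, …, s_N), where each sᵢ is the
arithmetic mean of the embedding vectors of the sentence's in-vocabulary
tokens:

* **local (first-order) coherence** — the cosine similarity of adjacent
  sentence vectors, averaged over the N−1 adjacent pairs:
  local(S) = Σᵢ₌₁^{N−1} cos(sᵢ, sᵢ₊₁) / (N−1).
* **global coherence** — the cosine similarity of each sentence vector to
  the centroid s̄ = (Σᵢ sᵢ)/N, averaged over all N sentences:
  global(S) = Σᵢ₌₁^{N} cos(sᵢ, s̄) / N.

Both metrics are descriptive statistics of vector geometry: they measure
how semantically similar consecutive sentences (local) or each sentence
and the overall drift of the passage (global) are, not whether the
discourse is intelligible.

A transcript holds four emotion sections (sadness, fear, anger,
happiness), each elicited by three fixed questions. Scores are computed
per section and averaged, unweighted, over the sections with defined
scores; with two embedding models this yields four metrics per
participant (local/global × model). A `question` aggregation mode
computes scores per question answer and averages those instead; the
section-level default treats an emotion's whole answer as one discourse.

### Denominator modes

Published variants of these formulas sometimes divide the (N−1)-term
local sum (and an (N−1)-term global sum) by N rather than by the number
of summed terms. The default modes (`pairs`, `terms`) divide by the
number of terms, so N identical sentences score exactly 1 and scores are
comparable across transcripts of different lengths. The `paper_verbatim`
modes reproduce the /N variants exactly (the identity case then scores
(N−1)/N). Both are first-class options; nothing downstream depends on
the choice.

### Missing values

MISSING is a value, never zero: a sentence with no in-vocabulary token is
excluded (it cannot enter a cosine as a zero vector); local coherence is
undefined for N < 2, global for N = 0 or a zero-norm centroid; a section
with no defined score simply does not contribute to the participant mean.
Downstream statistics use pairwise-complete observations (plain
correlations) or listwise-complete ones (partial correlations).

### Numerical choices

Cosines are clipped into [−1, 1] to absorb rounding at the boundary.
The global-coherence centroid and both score sums are computed with
exact (`math.fsum`) summation, which makes global coherence *bit-exactly*
invariant under sentence permutation rather than invariant only up to
summation order. Ties and degenerate inputs (empty answers, all-stopword
sentences, all-OOV sentences) degrade to counted, logged exclusions, not
errors.

## Preprocessing

The chain is fixed: verbal-filler removal → stopword removal →
lemmatization. Running lemmatization first could change lexicon
membership, so the order is deliberately not configurable. Lexicon
matching lowercases both sides (German stopwords appear capitalized
sentence-initially); emitted tokens keep their casing because embedding
models may be case-sensitive. Tokenization is whitespace splitting with
edge-punctuation stripping after Unicode NFC normalization — no case
folding, no morphological analysis. The lemmatizer is a pluggable
`str -> str` contract (identity and table-driven implementations ship;
a failing call keeps the surface form and logs).

The shipped German stopword (~190 entries) and filler (~14 entries)
lists are versioned resource files. Results are sensitive to these
inventories; studies wanting exact comparability must supply their own
files, which is why every test passes explicit toy lexicons instead of
relying on the defaults.

### Sentence annotation

The reference path is **marker mode**: sentence boundaries were placed by
a human annotator as sentence-final punctuation, following the guideline
that a sentence contains at least a subject and a verb, main clauses keep
their subordinate clauses, incomplete main clauses are closed with a
period, and coordinated main clauses are separated. **Automatic mode** is
a rule-based approximation: the same punctuation split plus a split at
commas directly followed by a listed coordinating conjunction (und, aber,
oder, …); it never splits at subordinating-conjunction commas and does
not verify subject+verb presence (no syntactic parsing). Token
conservation holds in both modes: the multiset of tokens across sentences
equals the tokenization of the raw answer.

## Embedding models

Vector files are read in the two common text dialects (word2vec-text
with a `<vocab> <dim>` header; GloVe-text without), auto-detected by the
header line; binary word2vec is out of scope. OOV policy for
case-sensitive models: exact match, then a single lowercase fallback
(configurable off), then OOV. Both study-style static embeddings and the
package's toy models go through the same `EmbeddingModel` interface —
the pipeline treats any word → vector map of fixed dimension uniformly.

## Synthetic data: what it emulates, and what it does not

No patient recordings ship with the package, so validation rests on a
generative model whose ground truth is known.

**Topic space.** `n_topics` unit centers (orthonormal when n_topics ≤
dim, otherwise rejection-sampled under a pairwise-cosine ceiling), each
with `vocab_per_topic` word vectors: center plus isotropic Gaussian noise
of total power 1/`dispersion`, renormalized. Function words (drawn from
the shipped stopword/filler lists so preprocessing engages) get
unstructured random vectors. Defaults: 4 topics, dim 50, 50 words per
topic, dispersion 8 (within-topic mean cosine ≈ 0.89, between ≈ 0).

**Topic-drift transcripts.** Each sentence samples words from a latent
topic that switches to a uniformly random other topic with probability
`p_switch` per sentence; words are topic words, stopwords (rate 0.30) or
fillers (rate 0.04). Defaults — 3 questions × 2–3 sentences × 5–11 words
per emotion section — give raw transcripts of ≈240 words with ≈140
distinct words, the scale of real semi-structured emotion interviews.
`p_switch` is the ground-truth incoherence dial: mean local coherence
falls monotonically from ≈0.97 (p_switch = 0) to ≈0 (p_switch = 1).

**Simulated cohorts.** Per-participant switch rates are drawn from
Beta(1.5, 6) (mean 0.2, right-skewed — wide clinical heterogeneity);
the standardized negative switch rate is the latent coherence. Each
outcome is linked linearly: outcome = mean + sd·(ρ·z + √(1−ρ²)·ε),
the simplest structure realizing a target Pearson ρ. Default links use
outcome scales and effect magnitudes typical of clinical validation
samples (PANSS-factor means/SDs, |ρ| ≈ 0.1–0.3); day-count outcomes are
clipped at zero, which mildly attenuates their realized ρ — the
ground-truth table records the realized value. T2 columns follow an
AR(1)-style link to T1 (autocorrelation 0.7). One root seed fans out to
named CRC32-derived streams, so generators are independently
reproducible.

**What passing tests do not show.** The generator produces token
sequences with topic geometry, not German; it has no syntax, no
disfluency structure beyond i.i.d. fillers, no rater noise in the
clinical measures, and its embedding "model" is noise around ideal
centers rather than a trained distributional model. Parameter-recovery
results therefore demonstrate that the pipeline measures what the
generative model encodes — not that the metrics are clinically valid on
real speech. Measurement attenuation is visible even here: with ~25–30
sentences per transcript the scored local coherence correlates ≈0.87
with the latent switch rate, so a latent-outcome link of ρ = −0.30 is
recovered at r ≈ −0.21 … −0.35 depending on the seed.

## Statistics layer

Pearson correlations (scipy) with two-sided p from the t transform;
partial correlations by residualizing both variables on the controls
(least squares with intercept) and correlating residuals, p with
n−2−k df — verified against the inverse-correlation-matrix formula and
against `pingouin` in tests. Group differences use Welch's t-test by
default (the variance assumption is rarely defensible in clinical
samples); the pooled form is available by flag. All p-values are
descriptive: the analyses are exploratory, many parameters are examined,
and no multiple-testing correction is applied — the rendered report
carries that caveat in its banner. Significance markers (* p < 0.05,
** p < 0.01) are display conventions only.

## Design choices that were genuinely open

* **Aggregation granularity** — section-level scoring is the default;
  question-level is a mode, because elicitation-question answers are
  short (often 1–2 sentences) and local coherence is undefined below two
  sentences, so question-level aggregation discards more data.
* **Marker vs automatic annotation** — manual boundaries are the
  reference; the automatic splitter exists for unannotated text and is
  documented as an approximation, not an equivalent.
* **Raw-count reporting** — transcript length and unique-word counts are
  reported over raw annotated tokens (before filtering), with the
  post-filter count alongside, so length-confound screens use the
  quantity a transcriber would report.
* **Problem sizes** — simulation-based checks use 100 transcripts per
  condition and 500-participant cohorts: large enough that the r-sampling
  standard error (≈0.04 at n = 500) is small against the effects probed,
  small enough to run interactively.

## Known limitations

Static word embeddings only (no contextual models); no tangentiality or
question-relevance metrics; no audio or transcription stage; the
automatic sentence splitter does not parse syntax; the exact stopword and
filler inventories of any given study must be supplied to reproduce its
preprocessing; clipping of nonnegative outcomes slightly biases their
realized correlations toward zero.
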