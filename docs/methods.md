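# Methods

## Problem and design

`carefair` audits counterfactual gender fairness in text summarisation of
long-term care records. The unit of analysis is a counterfactual pair: two
versions of the same care note, identical except for gendered tokens. Both
versions are summarised by every model under audit at every output-length
cap, and any systematic difference between the female and male summaries is
attributed to the summariser, because the inputs are constructed (and
validated) to be gender-equivalent.

The full factorial design is documents x 2 genders x models x max-token
levels. With the reference configuration of 4 models and 6 levels this is
48 summaries per document. The max-token factor includes an uncapped level,
carried as the sentinel string `"None"` so it is a first-class factor level
throughout.

## Corpus preparation

Eligibility filtering keeps notes of 200-500 whitespace tokens (after NFKC
and whitespace normalisation; the counter is deliberately simple and
documented because different tokenisers disagree near the boundaries) and
drops notes containing configurable exclusion terms — sex-specific anatomy
and domestic violence, situations that do not transfer across a gender
swap. Near-duplicates are removed by word 5-shingle Jaccard similarity at
threshold 0.9, keeping the earlier document in input order.

Gender swapping is deterministic and rule-based: a bidirectional lexicon of
gendered forms (pronouns, titles, kinship and person nouns) with case
preservation. The ambiguous token "her" is resolved by local context: "her"
followed by a verb or a phrase-initial function word (or a clause boundary)
is the objective pronoun and maps to "him"; "her" followed by a content
word is the possessive determiner and maps to "his". The reverse direction
collapses "his"/"him" to "her" and maps "Mr" to "Mrs" by default; both
collapses (and Ms/Miss to Mr) are lossy and logged. An LLM-based swapper can
be plugged in behind the same operation contract; the rule-based default
keeps the pipeline reproducible and download-free.

Pair validation mirrors the construction guarantee: a pair is validated iff
both versions have the same number of sentences and, per aligned sentence,
the same count of non-stop-word, non-gendered tokens. The stop-word list,
sentence-splitting rules, verb list and dictionary snapshot are shipped as
versioned data files so validation is bit-stable across machines (no
external NLP runtime is required or used).

## Summarisation harness

Summarisers plug in behind `SummarizerSpec`: a callable
`(text, max_tokens_level, cell) -> summary`. The shipped defaults are
extractive mocks — first k sentences per level (k = 1, 2, 3, 4, 6, all) —
so every downstream statistic has a known null: on validated pairs the
deterministic mock produces summaries identical across genders up to
gendered tokens, and all bias statistics sit exactly at their null. Real
model adapters (e.g. Hugging Face pipelines) satisfy the same contract but
are intentionally out of the test surface; decoding parameters beyond the
length cap are treated as opaque adapter configuration.

## Sentiment analysis

Metrics are per-sentence scorers (`sentence -> score`), binary in {0, 1} or
continuous in [0, 1]. The per-summary score is the mean of per-sentence
scores — the proportion of positive sentences for a binary metric. This
reconciles sentence-level metrics with a one-row-per-summary design matrix;
per-sentence scores are retained alongside. The shipped default is a
transparent signed-lexicon scorer, `0.5 + (pos - neg) / (2(pos + neg))`
over lemma hits in versioned positive/negative word lists, with a binary
variant. Whether a deployed metric should instead score the whole summary
in one call is metric-specific; the mean-of-sentences rule is the package's
fixed convention.

**Metric screening.** Before a metric is used on summaries it is screened
for intrinsic gender sensitivity by scoring the two versions of each
*original* pair and fitting the gender effect with a document random
intercept. A metric whose score is a function of the non-gendered token
multiset scores both versions identically and passes trivially; a metric
that reacts to gendered tokens fails (p below alpha, default 0.05) and
should not be used, since it would measure its own bias rather than the
summariser's. The paired mixed-intercept form was chosen over a paired
t-test to match the main model's clustering; with two observations per
document the two are essentially equivalent.

**Mixed model.** Per-summary sentiment is modelled as

    sentiment_ij = b0 + b1' model_j + b2 gender_j + b3'(model_j x gender_j)
                   + b4' max_tokens_j + u_0i + u_1i' model_j + e_ij

with gender coded 0 = female / 1 = male, reference levels BART (or the
alphabetically first model) and max-tokens 50, and per-document random
intercepts varying by model with unstructured covariance (implemented as
one indicator column per model in the random-effects design; this is the
u0 + u1 parametrisation up to a linear reparametrisation). Estimation is
statsmodels `MixedLM`; the default is ML rather than REML so that
likelihood-ratio tests of nested fixed-effect structures are valid.
Fixed-effect inference is Wald z — a deliberate, documented difference from
mixed-model software that prints t statistics; at the design sizes involved
the difference is negligible. Demographic covariates (age, ethnicity) are
supported as optional fixed effects but off by default. A constant outcome
(every summary scoring the same value) is detected and returned as the
exact degenerate fit rather than passed to the optimiser.

**EMM contrasts.** The reported quantity is the per-model estimated
marginal mean gender contrast (female - male) averaged over a balanced
max-tokens grid. Because max-tokens enters additively, the grid averaging
cancels and the contrast is exactly -(b2) for the reference model and
-(b2 + b3m) otherwise; its SE comes from the fixed-effect covariance by the
delta method. `emm_from_coefficients` applies the same algebra to
externally reported fixed effects.

**LRT and bootstrap.** `likelihood_ratio_test` requires nested fixed
effects on the same data and clips the statistic at zero.
`cluster_bootstrap` resamples documents (clusters) with replacement,
relabels resampled copies so duplicated documents remain distinct clusters,
refits, and reports percentile intervals; it is deterministic under seed.

## Inclusion bias (themes)

Theme lexicons (physical health, mental health, physical appearance,
subjective language) are plain-text lemma lists, shipped as editable
starter files and versioned. Counting is lemma-level, word-boundary and
case-insensitive; multi-word terms match as contiguous lemma sequences.
The default test per (model, theme) is a 1-df goodness-of-fit chi-square of
the (female, male) totals against equal expectation — justified when source
pairs use every term equally by gender, which validated pairs guarantee. An
exposure-adjusted 2x2 variant (term count vs all other tokens per gender)
is available behind a flag for unbalanced corpora. P-values are BH-adjusted
across the single family of all (theme x model) tests.

## Linguistic bias (words)

Summaries are reduced to a sparse lemma document-term matrix: stop words,
punctuation, numerals and out-of-dictionary lemmas removed; the vocabulary
is the union across genders so structural zeros are retained. The
dictionary is a shipped snapshot, which keeps vocabularies stable across
machines; terms outside it are excluded exactly as unknown tokens would be.

Two tests per lemma, combined by a dual criterion:

1. **Aggregate count test.** 2x2 chi-square of the lemma's count against
   all other tokens per gender, with per-gender token totals as exposure;
   Fisher's exact test replaces it when either gender's count is below 5
   ("fewer than 5" read literally as count < 5). A goodness-of-fit
   alternative on the raw count pair is available behind a flag. The BH
   family is all tested lemmas within one summarisation model. Lemmas with
   total count below 2 are untestable and skipped.
2. **Count regression.** Poisson with log link on
   `gender + max_tokens + doc_id` dummies, rows being all summary rows of
   documents where the lemma appears at least once (structural zeros within
   those documents retained, giving the within-document gender contrast).
   Estimation is Firth's penalised likelihood — the Jeffreys-prior penalty
   `l(b) + 1/2 log det I(b)` — via modified-score IRLS: for the canonical
   log link the adjusted score is `X'(y + h/2 - mu)` with h the hat
   diagonal, iterated with step halving, convergence at score norm 1e-8,
   at most 100 iterations. The penalty keeps estimates finite under perfect
   separation (words never used for one gender). SEs come from the inverse
   Fisher information at the optimum. No length offset is used: the
   max-tokens dummies absorb summary length (a documented divergence risk
   if level caps and realised lengths decouple). Document coefficients are
   estimated but never reported.

Overdispersion is diagnosed by the Pearson ratio `sum(r^2)/df_resid`; above
1.25 a maximum-likelihood negative binomial (NB2) with the same design
replaces the Poisson inference, falling back to the Firth fit (flagged) if
it fails to converge.

A lemma is flagged only when the regression p AND the BH-adjusted count
test p are both below alpha (default 0.05); the flagged set is therefore a
subset of both marginal significant sets by construction, and output is
sorted by |gender coefficient| within direction.

## Hallucination audit

A term scan over a versioned list of long-term-care diagnoses, lemma-level
with word boundaries (so "dementias" matches "dementia" but "demented" does
not, and substrings never match). A term is a hallucination in a summary iff
present in the summary and absent from that summary's own source version.
The opportunity space is documents x versions x parameter sets x terms.
Negation is not parsed ("no history of dementia" counts as present) — a
known limitation of the plain scan. Counts are only meaningful alongside
the term-list version, which the outputs record.

## Synthetic data generator

The generator is first-class, tested code, and its defaults define the
study conditions for the test bed: 400 documents, 8-12 sentences each,
assembled from themed sentence pools plus neutral filler with gendered
slots realised in parallel — so every pair is gender-equivalent by
construction and passes validation. Each themed pool sentence is included
with probability 0.5. All randomness is seeded; the seed is mandatory.

Bias is injected at summarisation time, never in the sources, matching the
causal structure the pipeline assumes (equivalent inputs, differences arise
in summaries). The biased mock summariser supports: per-(theme, gender)
sentence-drop probabilities (inclusion bias), per-occurrence phrase
substitutions targeted at one gender (linguistic bias; sources containing
gendered tokens are rejected because they would break comparability),
per-gender sentiment-shift sentence appends, and per-gender hallucination
rates that append a diagnosis no template ever uses. Every cell's
randomness derives from (root seed, doc, gender, model, level), so reruns
are byte-identical regardless of call order.

One generator control exists purely for null calibration:
`random_selection` makes the extractive mock sample k sentences at random
per cell instead of taking the first k. With the default deterministic
mock, female and male summaries are exactly equivalent and every null
p-value is degenerate at 1; random selection emulates the document-level
variation that stochastic decoding produces in real LLM output, giving a
non-degenerate null under which error control is actually testable. It is
off by default, preserving the exact null-configuration identity with the
plain mock.

What the generator does **not** emulate: clinical realism, vocabulary
breadth, discourse structure, abstractive paraphrase, or metric
miscalibration on real language. Passing tests therefore demonstrate that
the statistical machinery detects planted effects of stated sizes and
controls false positives under a controlled null — not that any particular
real LLM is biased or unbiased.

## Numerical and problem-size choices

* Mixed-model simulations for recovery/coverage use 200 documents, 2
  models and 3 max-token levels; LRT calibration uses 40-60 documents with
  2 models and 2 levels. These sizes give well-behaved likelihoods and are
  the package's chosen desk-scale defaults for its own verification runs.
* Null and power corpus runs use one mock model and 2-3 levels; the
  substitution-bias run uses 200 documents, the inclusion-bias run 400.
* Firth iteration: tolerance 1e-8 on the score norm, max 100 iterations,
  linear predictor clipped at +/-30 inside step halving to avoid overflow.
* Chi-square tests use no continuity correction; Fisher tests are
  two-sided.
* Ties in the binary lexicon metric (equal positive and negative hits)
  score 0 (not positive); sentences with no lexicon hits score 0.5 on the
  continuous metric.
* BH adjustment passes NaN (untestable) entries through without counting
  them toward the family size.

## Known limitations

* The "her" disambiguation is a heuristic; unusual syntax can misroute
  possessive vs objective uses. Such pairs fail validation downstream
  rather than contaminating the analysis.
* "Miss" as a verb is indistinguishable from the title in the rule-based
  swapper's token view.
* The dictionary snapshot bounds the analysable vocabulary; real-corpus
  deployments should extend it (one word per line) and record the version.
* The mixed model's Wald z inference is anti-conservative relative to
  Satterthwaite t at very small document counts.
* Hallucination scanning has no negation or uncertainty handling.
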