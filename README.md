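# carefair

Counterfactual gender-bias audit for text summarisation of long-term care
records.

Health and care services increasingly use language models to summarise
free-text case notes ("pen portraits"). If a summariser systematically
downplays one gender's needs — more negative sentiment, omitted health
topics, more euphemistic language — those differences can propagate into
allocation decisions. `carefair` is a reusable pipeline for quantifying
such bias, aimed at analysts and researchers who can run models over their
own (often restricted) care records.

## What it computes

The audit rests on counterfactual fairness: a summariser is fair towards an
individual if its output distribution is unchanged when only the protected
attribute is altered,

    P(Ŷ_{A←a} = y | A = a, X = x) = P(Ŷ_{A←a'} = y | A = a, X = x)  for all y.

Operationally, each care note is paired with a gender-swapped version that
is validated to be identical except for gendered tokens; both versions are
summarised by every model at every output-length cap, and four analyses
quantify differences:

1. **Sentiment.** Per-summary sentiment (mean of per-sentence metric
   scores) is modelled with a linear mixed model

       sentiment_ij = β₀ + β₁ᵀ model_j + β₂ gender_j + β₃ᵀ(model_j × gender_j)
                      + β₄ᵀ max_tokens_j + u₀ᵢ + u₁ᵢᵀ model_j + ε_ij

   with per-document random intercepts varying by model. The headline
   quantity is the per-model estimated-marginal-mean gender contrast
   (female − male), which is −β₂ for the reference model and −(β₂ + β₃ₘ)
   otherwise. Candidate metrics are first screened on the *original* pairs:
   a metric that scores gender-swapped but otherwise identical texts
   differently is excluded.
2. **Inclusion bias.** Counts of theme-lexicon terms (physical health,
   mental health, physical appearance, subjective language) per model and
   gender, tested by a 1-df χ² against equal expectation and
   Benjamini–Hochberg adjusted across the (theme × model) family.
3. **Linguistic bias.** A lemma document-term matrix feeds a dual
   criterion per word: a Firth-penalised Poisson regression
   `log E[count] = β₀ + β₁ gender + β₂ᵀ max_tokens + β₃ᵀ doc_id`
   (negative binomial when the Pearson dispersion ratio exceeds 1.25) AND a
   BH-adjusted χ²/Fisher count test; a word is flagged only when both are
   significant at α = 0.05.
4. **Hallucination.** Medical terms present in a summary but absent from
   its source, tallied by gender over the full opportunity space
   (documents × versions × parameter sets × terms).

Summarisers and sentiment metrics are plug-ins (`SummarizerSpec`,
`SentimentMetricSpec`); the shipped defaults are deterministic extractive
mocks and a transparent signed-lexicon scorer, so the whole pipeline runs
with no model downloads. A seeded synthetic-data generator produces
validated counterfactual pairs with controllable injected bias (sentence
dropping by theme, phrase substitution, sentiment shift, hallucination
rate), giving every stage a ground-truth test bed.

## Worked example

Audit a deliberately biased mock summariser on synthetic pairs — it drops
physical-health sentences for women 40% of the time and appends a negative
sentence to male summaries 30% of the time:

```python
from carefair import (SyntheticConfig, generate_pairs, build_grid,
                      run_summarization, biased_mock_summarizer)
from carefair.sentiment import lexicon_metric, SentimentMixedModel, estimate_gender_emm
from carefair.themes import theme_bias_table

cfg = SyntheticConfig(seed=7, n_docs=150,
                      inclusion_drop_prob={("physical_health", "female"): 0.4},
                      sentiment_shift={"male": -0.3})
pairs = generate_pairs(cfg)
print(f"{len(pairs)} pairs, {sum(p.validated for p in pairs)} validated")

grid = build_grid([p.doc_id for p in pairs], ["gemma_mock"], ["50", "100", "None"])
records = run_summarization(pairs, biased_mock_summarizer(cfg), grid)

fit = SentimentMixedModel.from_records(records, lexicon_metric()).fit()
for e in estimate_gender_emm(fit):
    print(f"EMM female-male, {e.model_name}: {e.estimate:+.4f} (z={e.statistic:.1f}, p={e.p:.2g})")
print(theme_bias_table(records)[["theme", "count_female", "count_male", "p_adj"]]
      .to_string(index=False))
```

prints

```
150 pairs, 150 validated
EMM female-male, gemma_mock: +0.0492 (z=8.0, p=1.5e-15)
              theme  count_female  count_male        p_adj
    physical_health           708        1259 7.778683e-35
      mental_health           693         808 5.989078e-03
physical_appearance           572         572 1.000000e+00
subjective_language           848         848 1.000000e+00
```

Read: female summaries score 0.049 higher in sentiment than male summaries
of the same notes (the injected negative male sentences), and
physical-health terms appear roughly 0.56× as often for women (the injected
40% drop). The mental-health imbalance is real too: the appended negative
sentence contains "distressed", a mental-health lexicon term. The two
untouched themes sit exactly at their null. With all bias parameters at
zero, every contrast is 0 and every adjusted p is 1.

The same audit runs from the shell:

```
carefair run-all --out audit/ --seed 7 --n-docs 100
carefair simulate --n-docs 400 --seed 7 --out pairs.jsonl
carefair summarize --pairs pairs.jsonl --models mock_a,mock_b --out summaries.jsonl
carefair sentiment --summaries summaries.jsonl --pairs pairs.jsonl --metric lexicon --out report/
carefair themes --summaries summaries.jsonl --out themes.csv
carefair words --summaries summaries.jsonl --out words.csv
carefair hallucination --pairs pairs.jsonl --summaries summaries.jsonl --out halluc/
```

For real corpora, `carefair prepare --in corpus.jsonl --out pairs.jsonl
--report report.json` filters (200–500 words, exclusion terms,
near-duplicates), gender-swaps and validates; real summarisers and metrics
plug in behind the spec objects.

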