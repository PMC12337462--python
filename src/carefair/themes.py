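"""Inclusion bias: theme-lexicon term counting and per-theme gender tests.

For each (model, theme) the total frequency of every lexicon term in female
and male summaries is counted. Because validated source pairs use all terms
an equal number of times per gender, a count difference in the summaries is
attributable to the summariser. The default test is a one-degree-of-freedom
goodness-of-fit chi-square of the observed (female, male) counts against
equal expectation; an exposure-adjusted 2x2 variant is available for
unbalanced corpora. P-values are Benjamini-Hochberg adjusted across the
whole (theme x model) family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .harness import SummaryRecord
from .text import Lemmatizer, default_lemmatizer

logger = logging.getLogger(__name__)

__all__ = [
    "ThemeLexicon",
    "load_theme_lexicons",
    "count_term_occurrences",
    "count_theme_terms",
    "theme_chisq",
    "theme_chisq_2x2",
    "bh_adjust",
    "theme_bias_table",
]

DEFAULT_THEMES = ("physical_health", "mental_health", "physical_appearance", "subjective_language")


@dataclass
class ThemeLexicon:
    theme: str
    terms: tuple[str, ...]  # lowercase lemma phrases

    def __post_init__(self):
        terms = tuple(t.strip().lower() for t in self.terms if t.strip())
        if len(set(terms)) != len(terms):
            raise ValueError(f"duplicate terms in theme {self.theme!r}")
        if not terms:
            logger.warning("theme %s has an empty lexicon", self.theme)
        object.__setattr__(self, "terms", terms)


def load_theme_lexicons(directory: str | Path | None = None) -> list[ThemeLexicon]:
    """Load one plain-text lexicon per theme (one term per line). With no
    directory, the shipped starter lexicons are used."""
    out = []
    if directory is None:
        base = resources.files("carefair.data").joinpath("themes")
        for theme in DEFAULT_THEMES:
            text = base.joinpath(f"{theme}.txt").read_text(encoding="utf-8")
            out.append(ThemeLexicon(theme, tuple(_parse_terms(text))))
    else:
        for path in sorted(Path(directory).glob("*.txt")):
            out.append(ThemeLexicon(path.stem, tuple(_parse_terms(path.read_text(encoding="utf-8")))))
    return out


def _parse_terms(text: str) -> list[str]:
    terms = []
    for line in text.splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            terms.append(line)
    return terms


def count_term_occurrences(
    lemmas: Sequence[str], term: str, lemmatizer: Lemmatizer | None = None
) -> int:
    """Occurrences of a (possibly multi-word) lemma phrase as a contiguous
    subsequence of the document's lemma sequence."""
    lem = lemmatizer or default_lemmatizer()
    phrase = tuple(lem.lemma(t) for t in term.split())
    if not phrase:
        return 0
    n, k = len(lemmas), len(phrase)
    return sum(1 for i in range(n - k + 1) if tuple(lemmas[i : i + k]) == phrase)


def count_theme_terms(
    summaries: Sequence[SummaryRecord],
    lexicons: Iterable[ThemeLexicon] | None = None,
    lemmatizer: Lemmatizer | None = None,
) -> pd.DataFrame:
    """Per (model, theme): total lexicon-term counts in female and male
    summaries (lemma-level, word-boundary, case-insensitive)."""
    lex = list(lexicons) if lexicons is not None else load_theme_lexicons()
    lem = lemmatizer or default_lemmatizer()
    counts: dict[tuple[str, str, str], int] = {}
    lemma_cache: dict[tuple, list[str]] = {}
    for rec in summaries:
        key = rec.key
        if key not in lemma_cache:
            lemma_cache[key] = lem.lemmas(rec.summary_text)
        lemmas = lemma_cache[key]
        for tl in lex:
            c = sum(count_term_occurrences(lemmas, t, lem) for t in tl.terms)
            k = (rec.model_name, tl.theme, rec.gender)
            counts[k] = counts.get(k, 0) + c
    rows = []
    models = sorted({r.model_name for r in summaries})
    for m in models:
        for tl in lex:
            rows.append(
                {
                    "model": m,
                    "theme": tl.theme,
                    "count_female": counts.get((m, tl.theme, "female"), 0),
                    "count_male": counts.get((m, tl.theme, "male"), 0),
                }
            )
    return pd.DataFrame(rows)


def theme_chisq(count_female: int, count_male: int) -> tuple[float, float]:
    """1-df goodness-of-fit chi-square of (F, M) against equal expected
    counts; both counts zero is undefined and returned as NaN."""
    if count_female < 0 or count_male < 0:
        raise ValueError("counts must be non-negative")
    total = count_female + count_male
    if total == 0:
        return float("nan"), float("nan")
    e = total / 2.0
    stat = (count_female - e) ** 2 / e + (count_male - e) ** 2 / e
    return float(stat), float(stats.chi2.sf(stat, 1))


def theme_chisq_2x2(
    count_female: int, count_male: int, total_female: int, total_male: int
) -> tuple[float, float]:
    """Exposure-adjusted variant: 2x2 chi-square of term count vs all other
    tokens per gender (for corpora without balanced gender exposure)."""
    table = np.array(
        [
            [count_female, total_female - count_female],
            [count_male, total_male - count_male],
        ]
    )
    if (table < 0).any():
        raise ValueError("totals must be >= counts")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving with
    the input positions. NaNs pass through and do not count toward the
    family size."""
    arr = np.asarray(pvals, dtype=float)
    mask = ~np.isnan(arr)
    vals = arr[mask]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    out = np.full(arr.shape, np.nan)
    if vals.size:
        out[mask] = multipletests(vals, method="fdr_bh")[1]
    return out.tolist()


def theme_bias_table(
    summaries: Sequence[SummaryRecord],
    lexicons: Iterable[ThemeLexicon] | None = None,
    exposure_adjusted: bool = False,
) -> pd.DataFrame:
    """Theme-level gender tests across models with one BH family spanning
    all (theme x model) tests."""
    counts = count_theme_terms(summaries, lexicons)
    if exposure_adjusted:
        totals = {
            g: sum(len(r.summary_text.split()) for r in summaries if r.gender == g)
            for g in ("female", "male")
        }
        res = [
            theme_chisq_2x2(r.count_female, r.count_male, totals["female"], totals["male"])
            if (r.count_female + r.count_male) > 0
            else (float("nan"), float("nan"))
            for r in counts.itertuples()
        ]
    else:
        res = [theme_chisq(r.count_female, r.count_male) for r in counts.itertuples()]
    counts["chisq"] = [s for s, _ in res]
    counts["p"] = [p for _, p in res]
    counts["p_adj"] = bh_adjust(counts["p"])
    return counts
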