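"""Sentiment-based counterfactual bias analysis.

Per-summary sentiment (the mean of per-sentence metric scores; the
proportion of positive sentences for a binary metric) is modelled with a
linear mixed-effects model:

    sentiment_ij = b0 + b1' model_j + b2 gender_j + b3' (model_j x gender_j)
                   + b4' max_tokens_j + u_0i + u_1i' model_j + e_ij

with per-document random intercepts varying by summarisation model
(unstructured covariance) and gender coded 0 = female, 1 = male. The
quantity of interest is the per-model estimated marginal mean (EMM) gender
contrast, female - male, which is -(b2) for the reference model and
-(b2 + b3m) otherwise; its standard error follows from the fixed-effect
covariance by the delta method.

Candidate sentiment metrics are screened for intrinsic gender bias by
scoring the two versions of each *original* (pre-summarisation) pair: a
metric that scores gender-swapped but otherwise identical texts differently
measures its own bias, not the summariser's, and is excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

from .corpus import CounterfactualPair
from .harness import SummaryRecord, GENDERS
from .text import default_lemmatizer, load_wordlist, split_sentences

logger = logging.getLogger(__name__)

__all__ = [
    "SentimentMetricSpec",
    "lexicon_metric",
    "binary_lexicon_metric",
    "get_metric",
    "score_summaries",
    "MetricScreenResult",
    "screen_metric_bias",
    "SentimentMixedModel",
    "SentimentMixedModelResults",
    "fit_sentiment_mixed_model",
    "EmmContrast",
    "estimate_gender_emm",
    "emm_from_coefficients",
    "likelihood_ratio_test",
    "cluster_bootstrap",
    "simulate_sentiment_table",
]


# -- metrics -------------------------------------------------------------------

@dataclass
class SentimentMetricSpec:
    """Per-sentence sentiment scorer plug-in.

    score_type 'binary' scorers return 0/1 per sentence (1 = positive);
    'continuous' scorers return values in [0, 1].
    """

    name: str
    score_sentence: Callable[[str], float]
    score_type: str = "continuous"

    def score_text(self, text: str) -> float:
        sents = split_sentences(text)
        if not sents:
            raise ValueError("text has no sentences")
        return float(np.mean([self._checked(s) for s in sents]))

    def _checked(self, sentence: str) -> float:
        v = float(self.score_sentence(sentence))
        if self.score_type == "binary" and v not in (0.0, 1.0):
            raise ValueError(f"binary metric {self.name!r} returned {v}")
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"metric {self.name!r} returned {v} outside [0, 1]")
        return v


def _lexicon_polarity(sentence: str, pos: frozenset, neg: frozenset) -> tuple[int, int]:
    lem = default_lemmatizer()
    lemmas = lem.lemmas(sentence)
    return sum(l in pos for l in lemmas), sum(l in neg for l in lemmas)


def lexicon_metric() -> SentimentMetricSpec:
    """Transparent signed-lexicon scorer: 0.5 + (pos - neg) / (2 (pos + neg))
    over lemma hits in the shipped positive/negative word lists."""
    pos = frozenset(load_wordlist("sentiment_positive.txt"))
    neg = frozenset(load_wordlist("sentiment_negative.txt"))

    def score(sentence: str) -> float:
        p, n = _lexicon_polarity(sentence, pos, neg)
        if p + n == 0:
            return 0.5
        return 0.5 + 0.5 * (p - n) / (p + n)

    return SentimentMetricSpec("lexicon", score, "continuous")


def binary_lexicon_metric() -> SentimentMetricSpec:
    """Binary variant: a sentence is positive when positive hits outnumber
    negative hits; the per-summary score is the proportion positive."""
    pos = frozenset(load_wordlist("sentiment_positive.txt"))
    neg = frozenset(load_wordlist("sentiment_negative.txt"))

    def score(sentence: str) -> float:
        p, n = _lexicon_polarity(sentence, pos, neg)
        return 1.0 if p > n else 0.0

    return SentimentMetricSpec("lexicon_binary", score, "binary")


_METRIC_REGISTRY: dict[str, Callable[[], SentimentMetricSpec]] = {
    "lexicon": lexicon_metric,
    "lexicon_binary": binary_lexicon_metric,
}


def get_metric(name: str) -> SentimentMetricSpec:
    try:
        return _METRIC_REGISTRY[name]()
    except KeyError:
        raise KeyError(f"unknown metric {name!r}; registered: {sorted(_METRIC_REGISTRY)}")


def score_summaries(
    records: Sequence[SummaryRecord], metric: SentimentMetricSpec
) -> pd.DataFrame:
    """One sentiment score per summary (sentence-mean), with full design
    annotations. Per-sentence scores are retained in 'sentence_scores'."""
    if not records:
        raise ValueError("no summary records to score")
    rows = []
    for r in records:
        sents = split_sentences(r.summary_text)
        if not sents:
            raise ValueError(f"summary {r.key} has no sentences")
        per_sent = [metric._checked(s) for s in sents]
        rows.append(
            {
                "doc_id": r.doc_id,
                "model": r.model_name,
                "gender": r.gender,
                "max_tokens": r.max_tokens_level,
                "sentiment": float(np.mean(per_sent)),
                "n_sentences": len(sents),
                "sentence_scores": per_sent,
                "metric": metric.name,
            }
        )
    return pd.DataFrame(rows)


# -- metric screening ----------------------------------------------------------

@dataclass
class MetricScreenResult:
    metric: str
    estimate: float
    p: float
    alpha: float
    passed: bool


def screen_metric_bias(
    pairs: Sequence[CounterfactualPair],
    metric: SentimentMetricSpec,
    alpha: float = 0.05,
) -> MetricScreenResult:
    """Test the metric itself for gender sensitivity on the original pair
    texts (male effect on score, document random intercept). A metric that
    sees only non-gendered tokens scores both versions identically and
    passes trivially."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs to screen a metric")
    rows = []
    for p in pairs:
        for g in GENDERS:
            rows.append(
                {"doc_id": p.doc_id, "gender": g, "score": metric.score_text(p.text_for(g))}
            )
    df = pd.DataFrame(rows)
    diffs = (
        df.pivot(index="doc_id", columns="gender", values="score")
        .eval("male - female")
        .to_numpy()
    )
    if np.allclose(diffs, 0.0):
        return MetricScreenResult(metric.name, 0.0, 1.0, alpha, 1.0 >= alpha)
    endog = df["score"].to_numpy()
    exog = sm.add_constant((df["gender"] == "male").astype(float).to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(endog, exog, groups=df["doc_id"].to_numpy()).fit(reml=True)
    est = float(fit.fe_params[1])
    pval = float(fit.pvalues[1])
    return MetricScreenResult(metric.name, est, pval, alpha, pval >= alpha)


# -- mixed model -----------------------------------------------------------------

def _design(
    table: pd.DataFrame, ref_model: str, ref_level: str, interactions: bool = True
) -> tuple[np.ndarray, pd.Index, list[str], list[str]]:
    models = sorted(table["model"].unique())
    levels = list(dict.fromkeys(table["max_tokens"].astype(str)))
    if ref_model not in models:
        raise ValueError(f"reference model {ref_model!r} not in data")
    if ref_level not in levels:
        raise ValueError(f"reference max-tokens level {ref_level!r} not in data")
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(table))}
    male = (table["gender"] == "male").to_numpy(float)
    for m in models:
        if m != ref_model:
            cols[f"model[{m}]"] = (table["model"] == m).to_numpy(float)
    cols["gender[male]"] = male
    if interactions:
        for m in models:
            if m != ref_model:
                cols[f"model[{m}]:gender[male]"] = cols[f"model[{m}]"] * male
    for l in levels:
        if l != ref_level:
            cols[f"max_tokens[{l}]"] = (table["max_tokens"].astype(str) == l).to_numpy(float)
    X = pd.DataFrame(cols, index=table.index)
    return X.to_numpy(), pd.Index(X.columns), models, levels


@dataclass
class SentimentMixedModelResults:
    """Fitted Eq.-style sentiment mixed model: fixed effects with Wald z
    inference, random-effect covariance, log-likelihood."""

    fe_params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    cov_fe: pd.DataFrame
    cov_re: np.ndarray
    scale: float
    llf: float
    converged: bool
    model_names: list[str]
    ref_model: str
    levels: list[str]
    ref_level: str
    nobs: int
    n_groups: int
    reml: bool
    metric: str = ""

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.fe_params / self.bse

    def summary(self) -> str:
        lines = [
            f"Sentiment mixed model ({'REML' if self.reml else 'ML'}), "
            f"{self.nobs} rows, {self.n_groups} documents"
            + (f", metric={self.metric}" if self.metric else ""),
            f"log-likelihood {self.llf:.3f}; converged={self.converged}",
            f"{'coef':<28}{'estimate':>12}{'std err':>10}{'z':>8}{'P>|z|':>10}",
        ]
        for name in self.fe_params.index:
            lines.append(
                f"{name:<28}{self.fe_params[name]:>12.4f}{self.bse[name]:>10.4f}"
                f"{self.zvalues[name]:>8.2f}{self.pvalues[name]:>10.3g}"
            )
        lines.append(f"residual variance {self.scale:.5g}")
        return "\n".join(lines)


class SentimentMixedModel:
    """Linear mixed model for per-summary sentiment over the factorial
    design, with per-document random intercepts varying by model.

    Parameters
    ----------
    table : DataFrame with columns doc_id, model, gender, max_tokens,
        sentiment (one row per design cell).
    ref_model, ref_level : reference factor levels (no dummy); default the
        alphabetically first model and level "50" when present.
    random_slopes : per-model random intercepts (unstructured covariance)
        when True; a single document intercept when False.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        ref_model: str | None = None,
        ref_level: str | None = None,
        random_slopes: bool = True,
        interactions: bool = True,
    ):
        req = {"doc_id", "model", "gender", "max_tokens", "sentiment"}
        if not req <= set(table.columns):
            raise ValueError(f"table must have columns {sorted(req)}")
        if table["doc_id"].nunique() < 2:
            raise ValueError("need at least 2 documents")
        if set(table["gender"].unique()) != set(GENDERS):
            raise ValueError("both genders are required (singular design otherwise)")
        self.table = table.reset_index(drop=True)
        models = sorted(self.table["model"].unique())
        levels = sorted(self.table["max_tokens"].astype(str).unique())
        self.ref_model = ref_model or ("bart" if "bart" in models else models[0])
        self.ref_level = ref_level or ("50" if "50" in levels else levels[0])
        self.random_slopes = random_slopes
        self.interactions = interactions

    @classmethod
    def from_records(
        cls, records: Sequence[SummaryRecord], metric: SentimentMetricSpec, **kw
    ) -> "SentimentMixedModel":
        return cls(score_summaries(records, metric), **kw)

    def fit(self, reml: bool = False, maxiter: int = 200) -> SentimentMixedModelResults:
        X, names, models, levels = _design(
            self.table, self.ref_model, self.ref_level, self.interactions
        )
        y = self.table["sentiment"].to_numpy(float)
        groups = self.table["doc_id"].to_numpy()
        if np.allclose(y, y[0]):
            # degenerate: constant outcome; exact closed form
            k = len(names)
            zero = pd.Series(np.zeros(k), index=names)
            params = zero.copy()
            params["Intercept"] = y[0]
            pv = pd.Series(np.ones(k), index=names)
            q = len(models) if self.random_slopes else 1
            return SentimentMixedModelResults(
                params, zero, pv, pd.DataFrame(np.zeros((k, k)), index=names, columns=names),
                np.zeros((q, q)), 0.0, np.inf, True, models, self.ref_model,
                levels, self.ref_level, len(y), len(set(groups)), reml,
            )
        if self.random_slopes:
            exog_re = np.column_stack(
                [(self.table["model"] == m).to_numpy(float) for m in models]
            )
        else:
            exog_re = np.ones((len(y), 1))
        model = MixedLM(y, X, groups=groups, exog_re=exog_re)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(reml=reml, maxiter=maxiter, method="lbfgs")
            except Exception:
                res = model.fit(reml=reml, maxiter=maxiter)
        k = len(names)
        fe = pd.Series(np.asarray(res.fe_params), index=names)
        cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k], index=names, columns=names)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=names)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = fe / bse
        pv = pd.Series(2 * stats.norm.sf(np.abs(z)), index=names)
        return SentimentMixedModelResults(
            fe, bse, pv, cov, np.asarray(res.cov_re), float(res.scale), float(res.llf),
            bool(res.converged), models, self.ref_model, levels, self.ref_level,
            len(y), len(set(groups)), reml, metric=str(self.table.get("metric", pd.Series([""])).iloc[0]),
        )


def fit_sentiment_mixed_model(table: pd.DataFrame, **kw) -> SentimentMixedModelResults:
    """Functional wrapper over SentimentMixedModel(...).fit()."""
    fit_kw = {k: kw.pop(k) for k in ("reml", "maxiter") if k in kw}
    return SentimentMixedModel(table, **kw).fit(**fit_kw)


# -- estimated marginal means ----------------------------------------------------

@dataclass
class EmmContrast:
    model_name: str
    metric: str
    estimate: float  # female - male
    se: float | None
    statistic: float | None
    p: float | None


def estimate_gender_emm(fit: SentimentMixedModelResults) -> list[EmmContrast]:
    """Per-model female-minus-male contrast averaged over a balanced
    max-tokens grid: -(b2) for the reference model, -(b2 + b3m) otherwise.
    The max-tokens terms cancel in the difference, so the contrast vector
    has -1 on gender[male] and -1 on the model's interaction term."""
    if not fit.converged:
        raise ValueError("cannot compute EMM contrasts from a non-converged fit")
    out = []
    for m in fit.model_names:
        c = pd.Series(0.0, index=fit.fe_params.index)
        c["gender[male]"] = -1.0
        inter = f"model[{m}]:gender[male]"
        if m != fit.ref_model:
            if inter not in c.index:
                raise ValueError(f"missing interaction term for model {m!r}")
            c[inter] = -1.0
        est = float(c @ fit.fe_params)
        if fit.cov_fe is not None:
            var = float(c @ fit.cov_fe @ c)
            se = float(np.sqrt(var)) if var > 0 else 0.0
            stat = est / se if se > 0 else np.inf * np.sign(est) if est else 0.0
            p = float(2 * stats.norm.sf(abs(stat))) if np.isfinite(stat) else 0.0
        else:
            se = stat = p = None
        out.append(EmmContrast(m, fit.metric, est, se, stat, p))
    return out


def emm_from_coefficients(
    coefficients: Mapping[str, float],
    models: Sequence[str],
    ref_model: str,
    metric: str = "",
) -> list[EmmContrast]:
    """EMM gender contrasts from externally reported fixed effects (keys
    'gender[male]' and 'model[<m>]:gender[male]'); no covariance, so SEs are
    not computed."""
    b2 = float(coefficients["gender[male]"])
    out = []
    for m in models:
        b3 = 0.0 if m == ref_model else float(coefficients.get(f"model[{m}]:gender[male]", 0.0))
        out.append(EmmContrast(m, metric, -(b2 + b3), None, None, None))
    return out


# -- LRT and bootstrap ------------------------------------------------------------

def likelihood_ratio_test(
    fit_full: SentimentMixedModelResults, fit_reduced: SentimentMixedModelResults
) -> tuple[float, int, float]:
    """2(ll_full - ll_reduced) against chi-square with df = parameter
    difference. Requires nested fixed effects fitted by ML on the same data."""
    full_names = set(fit_full.fe_params.index)
    red_names = set(fit_reduced.fe_params.index)
    if not red_names <= full_names:
        raise ValueError("models are not nested (reduced terms not a subset of full)")
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("fits are not on the same data")
    if fit_full.reml or fit_reduced.reml:
        logger.warning("LRT on REML fits is not valid for fixed-effect comparisons")
    df = len(full_names) - len(red_names)
    stat = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    if df == 0 and stat == 0.0:
        p = 1.0
    return stat, df, p


def cluster_bootstrap(
    table: pd.DataFrame,
    B: int,
    seed: int,
    ci: float = 0.95,
    **model_kw,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for the fixed effects, resampling documents
    (clusters) with replacement. Deterministic under seed."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    doc_ids = np.array(sorted(table["doc_id"].unique()))
    grouped = {d: g for d, g in table.groupby("doc_id")}
    draws = []
    for b in range(B):
        chosen = rng.choice(doc_ids, size=len(doc_ids), replace=True)
        parts = []
        for j, d in enumerate(chosen):
            g = grouped[d].copy()
            g["doc_id"] = f"bs{j}"  # copies become distinct clusters
            parts.append(g)
        bs = pd.concat(parts, ignore_index=True)
        fit = SentimentMixedModel(bs, **model_kw).fit()
        draws.append(fit.fe_params)
    mat = pd.DataFrame(draws)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    return pd.DataFrame(
        {
            "estimate": mat.mean(),
            "ci_low": mat.quantile(lo),
            "ci_high": mat.quantile(hi),
            "B": B,
        }
    )


# -- simulation -------------------------------------------------------------------

def simulate_sentiment_table(
    n_docs: int,
    models: Sequence[str] = ("bart", "gemma"),
    levels: Sequence[str] = ("50", "100", "300"),
    beta: Mapping[str, float] | None = None,
    re_sd: float = 0.05,
    re_corr: float = 0.3,
    sigma: float = 0.05,
    seed: int = 0,
    ref_model: str | None = None,
    ref_level: str | None = None,
) -> pd.DataFrame:
    """Simulate per-summary sentiment from the mixed model with known
    coefficients (keys as in the fitted design; missing terms are 0)."""
    rng = np.random.default_rng(seed)
    models = list(models)
    levels = [str(l) for l in levels]
    ref_model = ref_model or models[0]
    ref_level = ref_level or levels[0]
    rows = []
    for i in range(n_docs):
        for g in GENDERS:
            for m in models:
                for l in levels:
                    rows.append({"doc_id": f"d{i:04d}", "gender": g, "model": m, "max_tokens": l})
    df = pd.DataFrame(rows)
    X, names, _, _ = _design(df.assign(sentiment=0.0), ref_model, ref_level)
    b = np.zeros(len(names))
    for k, v in (beta or {}).items():
        if k not in list(names):
            raise KeyError(f"unknown coefficient {k!r}; valid: {list(names)}")
        b[list(names).index(k)] = v
    q = len(models)
    cov = re_sd**2 * ((1 - re_corr) * np.eye(q) + re_corr * np.ones((q, q)))
    u = rng.multivariate_normal(np.zeros(q), cov, size=n_docs)
    doc_index = df["doc_id"].str.slice(1).astype(int).to_numpy()
    model_idx = df["model"].map({m: j for j, m in enumerate(models)}).to_numpy()
    re_part = u[doc_index, model_idx]
    y = X @ b + re_part + rng.normal(0, sigma, len(df))
    df["sentiment"] = y
    return df
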