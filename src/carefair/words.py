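"""Linguistic bias: word-level count tests and per-word count regressions.

A word is flagged as used differently by gender only under a dual
criterion: (1) the gender coefficient in a per-word count regression is
significant, and (2) the Benjamini-Hochberg-adjusted chi-square / Fisher
test on aggregate counts is significant (adjusted p < alpha).

The count regression is Poisson with log link,

    log E[count_ij] = b0 + b1 gender_j + b2' max_tokens_j + b3' doc_id_j,

fitted by Firth's penalised likelihood (Jeffreys-prior penalty
l(b) + 1/2 log det I(b)) so that estimates stay finite under perfect
separation (words never used for one gender). Document fixed effects absorb
document-specific base rates and are estimated but not reported. When the
Pearson dispersion ratio sum(r_i^2)/df_resid exceeds 1.25 a negative
binomial regression with the same design replaces the Poisson inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .harness import SummaryRecord
from .text import Lemmatizer, default_lemmatizer, load_stopwords
from .themes import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "DocTermMatrix",
    "build_doc_term_matrix",
    "word_count_test",
    "WordRegressionResult",
    "firth_poisson",
    "fit_word_regression",
    "check_overdispersion",
    "fit_negative_binomial",
    "WordTestResult",
    "apply_dual_criterion",
    "analyze_linguistic_bias",
    "OVERDISPERSION_THRESHOLD",
]

OVERDISPERSION_THRESHOLD = 1.25


# -- document-term matrix --------------------------------------------------------

@dataclass
class DocTermMatrix:
    """Sparse lemma counts per summary row with design annotations."""

    counts: sparse.csr_matrix
    vocabulary: list[str]
    rows: pd.DataFrame  # doc_id, gender, model, max_tokens per matrix row

    def column(self, lemma: str) -> np.ndarray:
        j = self.vocabulary.index(lemma)
        return np.asarray(self.counts[:, j].todense()).ravel()

    def subset_model(self, model: str) -> "DocTermMatrix":
        mask = (self.rows["model"] == model).to_numpy()
        return DocTermMatrix(
            self.counts[mask], self.vocabulary, self.rows[mask].reset_index(drop=True)
        )

    def gender_totals(self, lemma: str) -> tuple[int, int]:
        col = self.column(lemma)
        male = (self.rows["gender"] == "male").to_numpy()
        return int(col[~male].sum()), int(col[male].sum())

    def token_totals(self) -> tuple[int, int]:
        row_sums = np.asarray(self.counts.sum(axis=1)).ravel()
        male = (self.rows["gender"] == "male").to_numpy()
        return int(row_sums[~male].sum()), int(row_sums[male].sum())

    def save(self, prefix: str | Path) -> None:
        """Persist as MTX triplets plus row-annotation CSV and vocabulary."""
        prefix = Path(prefix)
        from scipy.io import mmwrite

        mmwrite(str(prefix.with_suffix(".mtx")), self.counts)
        self.rows.to_csv(prefix.with_suffix(".rows.csv"), index=False)
        prefix.with_suffix(".vocab.txt").write_text("\n".join(self.vocabulary) + "\n")


def build_doc_term_matrix(
    summaries: Sequence[SummaryRecord],
    lemmatizer: Lemmatizer | None = None,
    extra_exclusions: Sequence[str] = (),
) -> DocTermMatrix:
    """Lemma counts per summary. Stop words, punctuation, numerals and
    out-of-dictionary lemmas are removed; the vocabulary is the union across
    genders, so structural zeros are retained."""
    lem = lemmatizer or default_lemmatizer()
    stop = load_stopwords()
    excl = set(extra_exclusions)
    docs_lemmas = []
    vocab_set: set[str] = set()
    for r in summaries:
        lemmas = [
            l
            for l in lem.lemmas(r.summary_text)
            if l.isalpha() and l not in stop and l not in excl and lem.is_dictionary_word(l)
        ]
        docs_lemmas.append(lemmas)
        vocab_set.update(lemmas)
    if not vocab_set:
        raise ValueError("empty vocabulary after filtering")
    vocabulary = sorted(vocab_set)
    index = {w: j for j, w in enumerate(vocabulary)}
    data, indices, indptr = [], [], [0]
    for lemmas in docs_lemmas:
        row_counts: dict[int, int] = {}
        for l in lemmas:
            j = index[l]
            row_counts[j] = row_counts.get(j, 0) + 1
        for j in sorted(row_counts):
            indices.append(j)
            data.append(row_counts[j])
        indptr.append(len(indices))
    counts = sparse.csr_matrix(
        (np.array(data, dtype=np.int64), np.array(indices), np.array(indptr)),
        shape=(len(summaries), len(vocabulary)),
    )
    rows = pd.DataFrame(
        {
            "doc_id": [r.doc_id for r in summaries],
            "gender": [r.gender for r in summaries],
            "model": [r.model_name for r in summaries],
            "max_tokens": [r.max_tokens_level for r in summaries],
        }
    )
    return DocTermMatrix(counts, vocabulary, rows)


# -- aggregate count tests --------------------------------------------------------

def word_count_test(
    count_female: int,
    count_male: int,
    total_female_tokens: int,
    total_male_tokens: int,
) -> tuple[str, float]:
    """2x2 test of a word's count against all other tokens per gender:
    chi-square when both counts are at least 5, Fisher's exact test when a
    count of fewer than 5 is observed for either gender."""
    if total_female_tokens < count_female or total_male_tokens < count_male:
        raise ValueError("totals must be >= counts")
    if count_female == 0 and count_male == 0:
        return "skipped", float("nan")
    table = np.array(
        [
            [count_female, total_female_tokens - count_female],
            [count_male, total_male_tokens - count_male],
        ]
    )
    if count_female < 5 or count_male < 5:
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return "fisher", float(p)
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return "chisq", float(p)


def word_count_test_gof(count_female: int, count_male: int) -> tuple[str, float]:
    """Goodness-of-fit alternative against equal expected counts (for
    corpora with balanced exposure); Fisher routing uses a binomial test."""
    if count_female == 0 and count_male == 0:
        return "skipped", float("nan")
    n = count_female + count_male
    if count_female < 5 or count_male < 5:
        p = stats.binomtest(count_female, n, 0.5).pvalue
        return "binom", float(p)
    e = n / 2.0
    stat = (count_female - e) ** 2 / e + (count_male - e) ** 2 / e
    return "chisq_gof", float(stats.chi2.sf(stat, 1))


# -- Firth-penalised Poisson regression -------------------------------------------

@dataclass
class WordRegressionResult:
    lemma: str
    beta_gender: float
    se_gender: float
    p_gender: float
    coefficients: pd.Series
    method: str  # firth_poisson | negative_binomial
    pearson_residuals: np.ndarray = field(repr=False, default=None)
    df_residual: int = 0
    dispersion_ratio: float = float("nan")
    converged: bool = True
    penalized_loglik: float = float("nan")


def firth_poisson(
    y: np.ndarray,
    X: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> tuple[np.ndarray, np.ndarray, bool, float]:
    """Maximise the Jeffreys-penalised Poisson log-likelihood
    l(b) + 1/2 log det(X'WX) by modified-score iteration.

    For the canonical log link the modified score is X'(y + h/2 - mu) with h
    the hat diagonal, i.e. IRLS on the pseudo-response y + h/2. Returns
    (beta, standard errors, converged, penalised log-likelihood)."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log(y.mean() + 0.5)  # intercept start at log mean
    converged = False
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = np.exp(eta)
        XtW = X.T * mu
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = mu * np.einsum("ij,jk,ik->i", X, info_inv, X)
        score = X.T @ (y + h / 2.0 - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        # step halving against divergence
        ll0 = _penalized_loglik(y, X, beta)
        lam = 1.0
        for _ in range(20):
            cand = beta + lam * step
            ll1 = _penalized_loglik(y, X, cand)
            if np.isfinite(ll1) and ll1 >= ll0 - 1e-12:
                break
            lam /= 2.0
        beta = beta + lam * step
    eta = np.clip(X @ beta, -30, 30)
    mu = np.exp(eta)
    info = (X.T * mu) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se, converged, _penalized_loglik(y, X, beta)


def _penalized_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    if np.max(eta) > 30:
        return -np.inf
    mu = np.exp(eta)
    ll = float(np.sum(y * eta - mu))  # constant -lgamma(y+1) omitted
    info = (X.T * mu) @ X
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def _regression_design(
    dtm: DocTermMatrix, lemma: str, ref_level: str | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Rows: every summary row of documents in which the lemma appears at
    least once (structural zeros inside those documents retained). Columns:
    intercept, gender, max-tokens dummies, document dummies."""
    col = dtm.column(lemma)
    docs_with = set(dtm.rows.loc[col > 0, "doc_id"])
    if not docs_with:
        raise ValueError(f"lemma {lemma!r} appears in no summary")
    mask = dtm.rows["doc_id"].isin(docs_with).to_numpy()
    y = col[mask].astype(float)
    sub = dtm.rows[mask]
    levels = sorted(sub["max_tokens"].astype(str).unique())
    ref = ref_level if ref_level in levels else ("50" if "50" in levels else levels[0])
    docs = sorted(docs_with)
    names = ["Intercept", "gender[male]"]
    cols = [np.ones(len(sub)), (sub["gender"] == "male").to_numpy(float)]
    for l in levels:
        if l != ref:
            names.append(f"max_tokens[{l}]")
            cols.append((sub["max_tokens"].astype(str) == l).to_numpy(float))
    for d in docs[1:]:
        names.append(f"doc[{d}]")
        cols.append((sub["doc_id"] == d).to_numpy(float))
    return y, np.column_stack(cols), names


def fit_word_regression(
    lemma: str, dtm: DocTermMatrix, ref_level: str | None = None
) -> WordRegressionResult:
    """Firth-penalised Poisson fit of the word-count design for one lemma;
    Wald inference on the gender coefficient."""
    y, X, names = _regression_design(dtm, lemma, ref_level)
    beta, se, converged, pll = firth_poisson(y, X)
    mu = np.exp(np.clip(X @ beta, -30, 30))
    resid = (y - mu) / np.sqrt(np.maximum(mu, 1e-12))
    df_resid = len(y) - X.shape[1]
    ratio = float(np.sum(resid**2) / df_resid) if df_resid > 0 else float("nan")
    j = names.index("gender[male]")
    z = beta[j] / se[j] if se[j] > 0 else np.inf * np.sign(beta[j])
    if not converged:
        logger.warning("Firth Poisson did not converge for lemma %r", lemma)
    return WordRegressionResult(
        lemma=lemma,
        beta_gender=float(beta[j]),
        se_gender=float(se[j]),
        p_gender=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
        coefficients=pd.Series(beta, index=names),
        method="firth_poisson",
        pearson_residuals=resid,
        df_residual=df_resid,
        dispersion_ratio=ratio,
        converged=converged,
        penalized_loglik=pll,
    )


def check_overdispersion(
    result: WordRegressionResult, threshold: float = OVERDISPERSION_THRESHOLD
) -> tuple[float, bool]:
    """Pearson dispersion ratio sum(r^2)/df_resid; flagged above threshold."""
    if result.df_residual <= 0:
        raise ValueError("df_residual must be positive to assess dispersion")
    ratio = float(np.sum(result.pearson_residuals**2) / result.df_residual)
    return ratio, ratio > threshold


def fit_negative_binomial(
    lemma: str, dtm: DocTermMatrix, ref_level: str | None = None
) -> WordRegressionResult:
    """Maximum-likelihood negative binomial (NB2, log link) with the same
    design; falls back to the Firth Poisson result when it fails."""
    from statsmodels.discrete.discrete_model import NegativeBinomial

    y, X, names = _regression_design(dtm, lemma, ref_level)
    if len(y) <= X.shape[1]:
        raise ValueError(f"insufficient residual df for lemma {lemma!r}")
    firth = fit_word_regression(lemma, dtm, ref_level)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = NegativeBinomial(y, X).fit(
                start_params=np.r_[firth.coefficients.to_numpy(), 0.1],
                disp=0,
                maxiter=200,
            )
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("NB did not converge")
    except Exception:
        logger.warning("negative binomial failed for %r; Firth Poisson retained", lemma)
        firth.converged = False
        return firth
    j = names.index("gender[male]")
    mu = np.exp(np.clip(X @ res.params[: len(names)], -30, 30))
    alpha = float(res.params[-1])
    resid = (y - mu) / np.sqrt(np.maximum(mu * (1 + alpha * mu), 1e-12))
    return WordRegressionResult(
        lemma=lemma,
        beta_gender=float(res.params[j]),
        se_gender=float(res.bse[j]),
        p_gender=float(res.pvalues[j]),
        coefficients=pd.Series(res.params[: len(names)], index=names),
        method="negative_binomial",
        pearson_residuals=resid,
        df_residual=len(y) - X.shape[1] - 1,
        dispersion_ratio=firth.dispersion_ratio,
        converged=True,
        penalized_loglik=float(res.llf),
    )


# -- dual criterion ----------------------------------------------------------------

@dataclass
class WordTestResult:
    lemma: str
    count_female: int
    count_male: int
    count_test: str
    p_raw: float
    p_adjusted: float
    p_regression: float
    beta_gender: float
    method: str
    dual_significant: bool

    @property
    def direction(self) -> str:
        return "male" if self.beta_gender > 0 else "female"


def apply_dual_criterion(
    regression_results: Mapping[str, WordRegressionResult],
    count_tests: Mapping[str, tuple[str, float]],
    counts: Mapping[str, tuple[int, int]],
    alpha: float = 0.05,
) -> list[WordTestResult]:
    """Flag lemmas significant in BOTH the regression and the BH-adjusted
    count test; sorted by |gender coefficient| descending within direction."""
    if set(regression_results) != set(count_tests):
        raise ValueError("regression and count-test vocabularies differ")
    lemmas = sorted(regression_results)
    adj = bh_adjust([count_tests[l][1] for l in lemmas])
    out = []
    for l, a in zip(lemmas, adj):
        reg = regression_results[l]
        test_used, p_raw = count_tests[l]
        cf, cm = counts[l]
        dual = bool(
            np.isfinite(a) and a < alpha and np.isfinite(reg.p_gender) and reg.p_gender < alpha
        )
        out.append(
            WordTestResult(
                l, cf, cm, test_used, p_raw, float(a), reg.p_gender,
                reg.beta_gender, reg.method, dual,
            )
        )
    out.sort(key=lambda r: (r.direction, -abs(r.beta_gender)))
    return out


def analyze_linguistic_bias(
    dtm: DocTermMatrix,
    model: str | None = None,
    alpha: float = 0.05,
    min_count: int = 2,
    exposure_adjusted: bool = True,
    check_dispersion: bool = True,
) -> pd.DataFrame:
    """Full word-level analysis for one summarisation model (the BH family):
    per-lemma count test + Firth Poisson regression (negative binomial on
    overdispersion), combined by the dual criterion."""
    sub = dtm.subset_model(model) if model is not None else dtm
    tf, tm = sub.token_totals()
    regs: dict[str, WordRegressionResult] = {}
    tests: dict[str, tuple[str, float]] = {}
    counts: dict[str, tuple[int, int]] = {}
    for lemma in sub.vocabulary:
        cf, cm = sub.gender_totals(lemma)
        if cf + cm < min_count:
            continue
        if exposure_adjusted:
            tests[lemma] = word_count_test(cf, cm, tf, tm)
        else:
            tests[lemma] = word_count_test_gof(cf, cm)
        counts[lemma] = (cf, cm)
        reg = fit_word_regression(lemma, sub)
        if check_dispersion and reg.df_residual > 0:
            _, flagged = check_overdispersion(reg)
            if flagged:
                try:
                    reg = fit_negative_binomial(lemma, sub)
                except ValueError:
                    pass
        regs[lemma] = reg
    results = apply_dual_criterion(regs, tests, counts, alpha)
    df = pd.DataFrame(
        {
            "lemma": [r.lemma for r in results],
            "count_female": [r.count_female for r in results],
            "count_male": [r.count_male for r in results],
            "direction": [r.direction for r in results],
            "coef": [r.beta_gender for r in results],
            "p_regression": [r.p_regression for r in results],
            "count_test": [r.count_test for r in results],
            "p_count_test": [r.p_raw for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "method": [r.method for r in results],
            "dual_significant": [r.dual_significant for r in results],
        }
    )
    if model is not None:
        df.insert(0, "model", model)
    return df


def simulate_word_counts(
    n_docs: int,
    levels: Sequence[str] = ("50", "100", "None"),
    beta_gender: float = 0.0,
    doc_sd: float = 0.5,
    base_rate: float = 1.0,
    level_effects: Mapping[str, float] | None = None,
    seed: int = 0,
    lemma: str = "word",
    dispersion: float = 0.0,
) -> DocTermMatrix:
    """Single-lemma count data simulated from the word-count regression with
    known gender effect (log rate ratio), per-document intercepts and
    max-tokens effects; dispersion > 0 switches to gamma-Poisson (negative
    binomial) noise for overdispersion studies."""
    rng = np.random.default_rng(seed)
    doc_eff = rng.normal(0, doc_sd, n_docs)
    levels = [str(l) for l in levels]
    lev_eff = {l: (level_effects or {}).get(l, 0.0) for l in levels}
    rows, y = [], []
    for i in range(n_docs):
        for g in ("female", "male"):
            for l in levels:
                eta = np.log(base_rate) + doc_eff[i] + (beta_gender if g == "male" else 0.0) + lev_eff[l]
                mu = np.exp(eta)
                if dispersion > 0:
                    mu = rng.gamma(1.0 / dispersion, dispersion * mu)
                y.append(rng.poisson(mu))
                rows.append({"doc_id": f"d{i:04d}", "gender": g, "model": "sim", "max_tokens": l})
    counts = sparse.csr_matrix(np.array(y, dtype=np.int64).reshape(-1, 1))
    return DocTermMatrix(counts, [lemma], pd.DataFrame(rows))
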