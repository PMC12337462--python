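import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from carefair.words import (
    WordRegressionResult,
    _penalized_loglik,
    analyze_linguistic_bias,
    apply_dual_criterion,
    build_doc_term_matrix,
    check_overdispersion,
    firth_poisson,
    fit_negative_binomial,
    fit_word_regression,
    simulate_word_counts,
    word_count_test,
)
from conftest import make_record


class TestDocTermMatrix:
    def test_lemma_counts_stopwords_removed(self):
        dtm = build_doc_term_matrix([make_record("She was walking and walked daily.")])
        assert dtm.column("walk").tolist() == [2]
        assert "she" not in dtm.vocabulary and "and" not in dtm.vocabulary

    def test_out_of_dictionary_excluded(self):
        dtm = build_doc_term_matrix([make_record("She walked zzqx daily."), make_record("More walking here.")])
        assert "zzqx" not in dtm.vocabulary

    def test_empty_summary_gives_zero_row(self):
        dtm = build_doc_term_matrix([make_record("Walking today."), make_record("12345 .")])
        assert np.asarray(dtm.counts[1].todense()).sum() == 0

    def test_vocabulary_shared_across_genders(self, small_records):
        dtm = build_doc_term_matrix(small_records)
        f = dtm.counts[(dtm.rows["gender"] == "female").to_numpy()]
        m = dtm.counts[(dtm.rows["gender"] == "male").to_numpy()]
        assert f.shape[1] == m.shape[1] == len(dtm.vocabulary)


class TestWordCountTest:
    def test_routing_rule(self):
        assert word_count_test(12, 5, 1000, 1000)[0] == "chisq"
        assert word_count_test(12, 4, 1000, 1000)[0] == "fisher"
        assert word_count_test(4, 12, 1000, 1000)[0] == "fisher"

    def test_fisher_matches_hypergeometric_enumeration(self):
        cf, cm, tf, tm = 3, 9, 1000, 1000
        _, p = word_count_test(cf, cm, tf, tm)
        # enumerate the hypergeometric null directly (two-sided by point mass)
        n = cf + cm
        rv = stats.hypergeom(tf + tm, n, tf)
        probs = [rv.pmf(k) for k in range(n + 1)]
        p_oracle = sum(q for q in probs if q <= probs[cf] * (1 + 1e-9))
        assert p == pytest.approx(p_oracle, rel=1e-6)

    def test_balanced_counts_null(self):
        test, p = word_count_test(50, 50, 5000, 5000)
        assert test == "chisq" and p == pytest.approx(1.0)

    def test_both_zero_skipped(self):
        test, p = word_count_test(0, 0, 100, 100)
        assert test == "skipped" and math.isnan(p)

    def test_totals_validated(self):
        with pytest.raises(ValueError):
            word_count_test(10, 2, 5, 100)


class TestFirthPoisson:
    def test_matches_brute_force_penalised_likelihood(self):
        # one document, two genders x two max-tokens levels
        y = np.array([3.0, 1.0, 0.0, 2.0])
        X = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1.0]])
        beta, _, converged, _ = firth_poisson(y, X)
        oracle = minimize(
            lambda t: -_penalized_loglik(y, X, t),
            np.zeros(3),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        assert converged
        assert np.max(np.abs(beta - oracle.x)) < 1e-4

    def test_finite_under_perfect_separation(self):
        dtm = simulate_word_counts(6, levels=("50", "None"), seed=3)
        # zero out male counts entirely: unpenalised MLE diverges
        col = dtm.counts.toarray()
        col[(dtm.rows["gender"] == "male").to_numpy(), :] = 0
        col[(dtm.rows["gender"] == "female").to_numpy(), :] += 1
        from scipy import sparse

        dtm.counts = sparse.csr_matrix(col)
        res = fit_word_regression("word", dtm)
        assert np.isfinite(res.beta_gender) and res.beta_gender < 0
        assert np.isfinite(res.se_gender)

    def test_gender_rate_ratio_recovered(self):
        rr = 1.5
        ests = []
        for seed in range(20):
            dtm = simulate_word_counts(100, beta_gender=np.log(rr), base_rate=1.5, seed=seed)
            ests.append(fit_word_regression("word", dtm).beta_gender)
        assert abs(np.mean(ests) - np.log(rr)) < 0.05

    def test_shrinks_toward_mle_with_sample_size(self):
        import statsmodels.api as sm

        diffs = []
        for n in (50, 500):
            dtm = simulate_word_counts(n, beta_gender=0.4, base_rate=2.0, doc_sd=0.0, seed=1)
            firth = fit_word_regression("word", dtm)
            from carefair.words import _regression_design

            y, X, names = _regression_design(dtm, "word")
            mle = sm.GLM(y, X, family=sm.families.Poisson()).fit()
            j = names.index("gender[male]")
            diffs.append(abs(firth.beta_gender - mle.params[j]))
        assert diffs[1] < diffs[0]


class TestOverdispersion:
    def test_arithmetic(self):
        res = WordRegressionResult(
            "w", 0, 1, 1, None, "firth_poisson",
            pearson_residuals=np.array([2.0, 2.0]), df_residual=2,
        )
        ratio, flagged = check_overdispersion(res)
        assert ratio == 4.0 and flagged

    def test_zero_residuals_not_flagged(self):
        res = WordRegressionResult(
            "w", 0, 1, 1, None, "firth_poisson",
            pearson_residuals=np.zeros(5), df_residual=3,
        )
        assert check_overdispersion(res) == (0.0, False)

    def test_df_guard(self):
        res = WordRegressionResult("w", 0, 1, 1, None, "firth_poisson",
                                   pearson_residuals=np.ones(2), df_residual=0)
        with pytest.raises(ValueError):
            check_overdispersion(res)

    def test_equidispersed_null_rarely_flagged(self):
        flags = 0
        for seed in range(60):
            dtm = simulate_word_counts(30, beta_gender=0.0, base_rate=2.0, seed=100 + seed)
            _, flagged = check_overdispersion(fit_word_regression("word", dtm))
            flags += flagged
        assert flags / 60 < 0.10


class TestNegativeBinomial:
    def test_agrees_with_poisson_when_equidispersed(self):
        dtm = simulate_word_counts(80, beta_gender=0.3, base_rate=2.0, seed=5)
        firth = fit_word_regression("word", dtm)
        nb = fit_negative_binomial("word", dtm)
        pooled_se = max(nb.se_gender, firth.se_gender)
        assert abs(nb.beta_gender - firth.beta_gender) < 2 * pooled_se

    def test_recovers_truth_under_overdispersion(self):
        truth = np.log(1.5)
        dtm = simulate_word_counts(150, beta_gender=truth, base_rate=3.0, dispersion=0.5, seed=6)
        nb = fit_negative_binomial("word", dtm)
        assert nb.method == "negative_binomial"
        assert abs(nb.beta_gender - truth) < 2 * nb.se_gender

    def test_insufficient_rows_rejected(self):
        dtm = simulate_word_counts(1, levels=("50",), seed=7)
        with pytest.raises(ValueError):
            fit_negative_binomial("word", dtm)


class TestDualCriterion:
    @staticmethod
    def _reg(lemma, p, beta=1.0):
        return WordRegressionResult(lemma, beta, 0.1, p, None, "firth_poisson")

    def test_conjunction_logic(self):
        regs = {"a": self._reg("a", 0.001), "b": self._reg("b", 0.5), "c": self._reg("c", 0.01)}
        tests = {"a": ("chisq", 0.001), "b": ("chisq", 0.001), "c": ("chisq", 0.9)}
        counts = {k: (5, 10) for k in regs}
        out = {r.lemma: r for r in apply_dual_criterion(regs, tests, counts, alpha=0.05)}
        assert out["a"].dual_significant
        assert not out["b"].dual_significant  # regression not significant
        assert not out["c"].dual_significant  # count test not significant

    def test_dual_set_subset_of_marginals(self):
        rng = np.random.default_rng(0)
        lemmas = [f"w{i}" for i in range(30)]
        regs = {l: self._reg(l, rng.uniform()) for l in lemmas}
        tests = {l: ("chisq", rng.uniform()) for l in lemmas}
        counts = {l: (3, 4) for l in lemmas}
        results = apply_dual_criterion(regs, tests, counts, alpha=0.2)
        dual = {r.lemma for r in results if r.dual_significant}
        reg_sig = {l for l in lemmas if regs[l].p_gender < 0.2}
        cnt_sig = {r.lemma for r in results if r.p_adjusted < 0.2}
        assert dual <= (reg_sig & cnt_sig)

    def test_vocabulary_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_dual_criterion({"a": self._reg("a", 0.5)}, {"b": ("chisq", 0.5)}, {"a": (1, 1)})


def test_analyze_unbiased_mock_flags_nothing(small_records):
    dtm = build_doc_term_matrix(small_records)
    df = analyze_linguistic_bias(dtm, "mock_a")
    # deterministic extractive mock: counts identical by gender
    assert (df["count_female"] == df["count_male"]).all()
    assert not df["dual_significant"].any()
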