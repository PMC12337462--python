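import numpy as np
import pandas as pd
import pytest

from carefair.corpus import CounterfactualPair, validate_pair
from carefair.sentiment import (
    SentimentMetricSpec,
    SentimentMixedModel,
    cluster_bootstrap,
    emm_from_coefficients,
    estimate_gender_emm,
    get_metric,
    lexicon_metric,
    likelihood_ratio_test,
    score_summaries,
    screen_metric_bias,
    simulate_sentiment_table,
)
from conftest import make_record


def constant_metric(value=1.0):
    return SentimentMetricSpec("const", lambda s: value)


class TestScoreSummaries:
    def test_constant_metric(self, small_records):
        table = score_summaries(small_records[:10], constant_metric())
        assert (table["sentiment"] == 1.0).all()

    def test_binary_metric_proportion(self):
        rec = make_record("Good one here. Bad one here. Good again here.")
        metric = SentimentMetricSpec("b", lambda s: 1.0 if "Good" in s else 0.0, "binary")
        table = score_summaries([rec], metric)
        assert table["sentiment"].iloc[0] == pytest.approx(2 / 3)
        assert table["sentence_scores"].iloc[0] == [1.0, 0.0, 1.0]

    def test_lexicon_metric_matches_hand_tally(self):
        # sentence 1: happy, settled -> (2 pos, 0 neg) -> 1.0
        # sentence 2: distressed, unhappy -> (0 pos, 2 neg) -> 0.0
        rec = make_record(
            "She is happy and settled with the arrangements. "
            "She is distressed and unhappy about the situation."
        )
        table = score_summaries([rec], lexicon_metric())
        assert table["sentiment"].iloc[0] == pytest.approx(0.5)

    def test_empty_summary_errors(self):
        with pytest.raises(ValueError):
            score_summaries([make_record("   ")], constant_metric())

    def test_binary_metric_range_check(self):
        bad = SentimentMetricSpec("bad", lambda s: 0.4, "binary")
        with pytest.raises(ValueError, match="binary"):
            score_summaries([make_record("A sentence here.")], bad)


class TestMetricScreening:
    def test_gender_blind_metric_passes(self, small_pairs):
        res = screen_metric_bias(small_pairs, lexicon_metric())
        assert res.passed and res.estimate == 0.0 and res.p == 1.0

    def test_gender_sensitive_metric_fails(self, small_pairs):
        def biased(sentence):
            toks = sentence.lower().split()
            return 0.6 if ("he" in toks or "his" in toks) else 0.4

        res = screen_metric_bias(small_pairs, SentimentMetricSpec("biased", biased), alpha=0.05)
        assert not res.passed
        assert res.estimate > 0

    def test_too_few_pairs(self, small_pairs):
        with pytest.raises(ValueError):
            screen_metric_bias(small_pairs[:1], lexicon_metric())

    def test_registry(self):
        assert get_metric("lexicon").name == "lexicon"
        with pytest.raises(KeyError):
            get_metric("siebert")


class TestMixedModel:
    def test_constant_outcome_degenerate_fit(self):
        sim = simulate_sentiment_table(5, seed=1)
        sim["sentiment"] = 0.37
        fit = SentimentMixedModel(sim).fit()
        assert fit.fe_params["Intercept"] == pytest.approx(0.37)
        assert np.allclose(fit.fe_params.drop("Intercept"), 0.0)
        assert np.allclose(fit.cov_re, 0.0) and fit.scale == 0.0

    def test_zero_random_effects_match_ols_oracle(self):
        sim = simulate_sentiment_table(
            40, beta={"Intercept": 0.3, "gender[male]": -0.02}, re_sd=0.0, sigma=0.05, seed=2
        )
        fit = SentimentMixedModel(sim).fit()
        import statsmodels.api as sm

        from carefair.sentiment import _design

        X, names, _, _ = _design(sim, fit.ref_model, fit.ref_level)
        ols = sm.OLS(sim["sentiment"].to_numpy(), X).fit()
        assert np.allclose(fit.fe_params.to_numpy(), ols.params, atol=1e-3)

    def test_known_gender_effect_recovered(self):
        beta2 = -0.01
        sim = simulate_sentiment_table(150, beta={"Intercept": 0.3, "gender[male]": beta2}, seed=3)
        fit = SentimentMixedModel(sim).fit()
        assert fit.converged
        est, se = fit.fe_params["gender[male]"], fit.bse["gender[male]"]
        assert abs(est - beta2) < 3 * se

    def test_single_gender_rejected(self):
        sim = simulate_sentiment_table(5, seed=4)
        with pytest.raises(ValueError, match="gender"):
            SentimentMixedModel(sim[sim.gender == "female"])


class TestEmmContrasts:
    def test_algebraic_identity_with_fit(self):
        sim = simulate_sentiment_table(
            30,
            beta={"gender[male]": -0.02, "model[gemma]:gender[male]": -0.01},
            seed=5,
        )
        fit = SentimentMixedModel(sim).fit()
        emm = {e.model_name: e for e in estimate_gender_emm(fit)}
        b2 = fit.fe_params["gender[male]"]
        b3 = fit.fe_params["model[gemma]:gender[male]"]
        assert emm[fit.ref_model].estimate == pytest.approx(-b2, abs=1e-12)
        assert emm["gemma"].estimate == pytest.approx(-(b2 + b3), abs=1e-12)

    def test_from_reported_coefficients(self):
        emm = emm_from_coefficients(
            {"gender[male]": 0.0036, "model[t5]:gender[male]": 0.0013},
            models=["bart", "t5"],
            ref_model="bart",
        )
        by = {e.model_name: e.estimate for e in emm}
        assert by["t5"] == pytest.approx(-0.0049)
        assert by["bart"] == pytest.approx(-0.0036)

    def test_null_coefficients_give_zero_contrasts(self):
        emm = emm_from_coefficients({"gender[male]": 0.0}, ["bart", "gemma"], "bart")
        assert all(e.estimate == 0.0 for e in emm)


class TestLrtAndBootstrap:
    def test_identical_models_lrt(self):
        sim = simulate_sentiment_table(20, seed=6)
        fit = SentimentMixedModel(sim).fit()
        stat, df, p = likelihood_ratio_test(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_interaction_lrt_runs(self):
        sim = simulate_sentiment_table(25, beta={"model[gemma]:gender[male]": -0.08}, seed=7)
        full = SentimentMixedModel(sim).fit()
        reduced = SentimentMixedModel(sim, interactions=False).fit()
        stat, df, p = likelihood_ratio_test(full, reduced)
        assert df == 1 and stat > 0 and p < 0.05

    def test_non_nested_rejected(self):
        sim = simulate_sentiment_table(10, seed=8)
        full = SentimentMixedModel(sim).fit()
        reduced = SentimentMixedModel(sim, interactions=False).fit()
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(reduced, full)

    def test_bootstrap_deterministic_and_degenerate(self):
        sim = simulate_sentiment_table(12, seed=9, levels=("50", "None"))
        a = cluster_bootstrap(sim, B=3, seed=11)
        b = cluster_bootstrap(sim, B=3, seed=11)
        pd.testing.assert_frame_equal(a, b)
        one = cluster_bootstrap(sim, B=1, seed=11)
        assert np.allclose(one["ci_low"], one["ci_high"])
        with pytest.raises(ValueError):
            cluster_bootstrap(sim, B=0, seed=1)
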