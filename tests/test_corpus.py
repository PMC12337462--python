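from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from carefair.corpus import (
    CareDocument,
    CounterfactualPair,
    dedupe_near,
    filter_eligible,
    make_pair,
    swap_gender,
    validate_pair,
)
from carefair.text import tokenize

TABLE_PAIR_F = (
    "Mrs Smith is an 87 year old, white British woman with reduced mobility. "
    "She cannot mobilise independently at home in her one-bedroom flat."
)
TABLE_PAIR_M = (
    "Mr Smith is an 87 year old, white British man with reduced mobility. "
    "He cannot mobilise independently at home in his one-bedroom flat."
)


def doc(i, n_words, extra=""):
    text = ("care " * n_words).strip() + (" " + extra if extra else "")
    return CareDocument(f"d{i}", text)


class TestFilterEligible:
    def test_word_count_boundaries(self):
        docs = [doc(i, n) for i, n in enumerate([199, 200, 500, 501])]
        kept, report = filter_eligible(docs, 200, 500, [])
        assert [d.doc_id for d in kept] == ["d1", "d2"]
        assert (report.n_too_short, report.n_too_long) == (1, 1)

    def test_exclusion_term(self):
        docs = [doc(0, 250, "a history of mastectomy was noted"), doc(1, 250)]
        kept, report = filter_eligible(docs, 200, 500)
        assert [d.doc_id for d in kept] == ["d1"]
        assert report.n_excluded_terms == 1

    def test_multiword_exclusion_term(self):
        docs = [doc(0, 250, "concerns about domestic violence were raised")]
        _, report = filter_eligible(docs, 200, 500)
        assert report.n_excluded_terms == 1

    def test_report_partitions_input(self):
        docs = [doc(i, n) for i, n in enumerate([10, 50, 150, 300, 300, 300, 300, 400, 450, 499])]
        kept, r = filter_eligible(docs, 200, 500, [])
        assert r.n_kept == 7 == len(kept)
        assert r.n_too_short + r.n_too_long + r.n_excluded_terms + r.n_kept == r.n_input == 10

    def test_empty_corpus(self):
        kept, r = filter_eligible([], 200, 500)
        assert kept == [] and r.n_input == 0 and r.n_kept == 0

    def test_missing_text_names_document(self):
        with pytest.raises(ValueError, match="dbad"):
            filter_eligible([CareDocument("dbad", "   ")], 1, 10)


class TestDedupeNear:
    def test_identical_documents(self):
        d = doc(0, 300)
        out = dedupe_near([d, CareDocument("d1", d.text)])
        assert [x.doc_id for x in out] == ["d0"]

    def test_one_word_changed_copy_removed(self):
        words = [f"w{i}" for i in range(300)]
        a = CareDocument("a", " ".join(words))
        changed = words.copy()
        changed[150] = "different"
        b = CareDocument("b", " ".join(changed))
        # brute-force oracle: shingle-set Jaccard computed directly
        sh = lambda toks: {tuple(toks[i : i + 5]) for i in range(len(toks) - 4)}
        sa, sb = sh(tokenize(a.text, True)), sh(tokenize(b.text, True))
        assert len(sa & sb) / len(sa | sb) >= 0.9
        assert [x.doc_id for x in dedupe_near([a, b], 5, 0.9)] == ["a"]

    def test_disjoint_vocabulary_both_kept(self):
        a = CareDocument("a", " ".join(f"x{i}" for i in range(50)))
        b = CareDocument("b", " ".join(f"y{i}" for i in range(50)))
        assert len(dedupe_near([a, b])) == 2

    @pytest.mark.parametrize("k", [2, 5])
    def test_multiplicity_invariance(self, k):
        d = doc(0, 250)
        docs = [CareDocument(f"d{i}", d.text) for i in range(k)]
        assert len(dedupe_near(docs)) == 1


class TestSwapGender:
    def test_reference_example(self, lexicon):
        assert swap_gender(TABLE_PAIR_F, lexicon, "f2m") == TABLE_PAIR_M

    def test_possessive_objective_disambiguation(self, lexicon):
        assert swap_gender("I saw her leave her coat.", lexicon, "f2m") == "I saw him leave his coat."

    def test_case_preserved(self, lexicon):
        assert swap_gender("SHE said Her mother visits.", lexicon, "f2m") == "HE said His father visits."

    def test_non_lexicon_tokens_byte_identical(self, lexicon):
        text = "The assessment on 2021-03-04 noted she needs support; carers attend twice."
        swapped = lexicon.swap(text, "f2m")
        kept = [t for t in tokenize(text) if not lexicon.is_gendered(t)]
        kept_after = [t for t in tokenize(swapped) if not lexicon.is_gendered(t)]
        assert kept == kept_after

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.sampled_from(
                ["she", "herself", "woman", "lady", "mother", "wife", "daughter", "care", "flat", "visit"]
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_round_trip_involution_on_unambiguous_tokens(self, lexicon, tokens):
        text = " ".join(tokens).capitalize() + "."
        assert lexicon.swap(lexicon.swap(text, "f2m"), "m2f") == text


class TestValidatePair:
    def test_reference_pair_validates(self, lexicon):
        pair = validate_pair(CounterfactualPair("p", TABLE_PAIR_F, TABLE_PAIR_M), lexicon)
        assert pair.validated

    def test_identical_texts_validate(self, lexicon):
        pair = validate_pair(CounterfactualPair("p", TABLE_PAIR_F, TABLE_PAIR_F), lexicon)
        assert pair.validated

    def test_appended_sentence_fails(self, lexicon):
        male = TABLE_PAIR_M + " He continues to make unwise decisions about his care needs."
        pair = validate_pair(CounterfactualPair("p", TABLE_PAIR_F, male), lexicon)
        assert not pair.validated
        assert pair.validation_detail["mismatch"] == "sentence_count"

    def test_extra_word_fails_with_sentence_index(self, lexicon):
        male = TABLE_PAIR_M.replace("reduced mobility", "severely reduced mobility")
        pair = validate_pair(CounterfactualPair("p", TABLE_PAIR_F, male), lexicon)
        assert not pair.validated
        assert pair.validation_detail["mismatch"] == "word_count"
        assert pair.validation_detail["sentence_index"] == 0

    def test_swapped_unambiguous_text_always_validates(self, lexicon):
        doc_ = CareDocument("d", TABLE_PAIR_F, gender_original="female")
        assert make_pair(doc_, lexicon).validated
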