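import pytest

from carefair.corpus import GenderLexicon
from carefair.harness import SummaryRecord, build_grid, mock_summarizer, run_summarization
from carefair.synthetic import SyntheticConfig, generate_pairs


@pytest.fixture(scope="session")
def lexicon():
    return GenderLexicon.from_tsv()


@pytest.fixture(scope="session")
def small_pairs():
    return generate_pairs(SyntheticConfig(seed=42, n_docs=12))


@pytest.fixture(scope="session")
def small_records(small_pairs):
    grid = build_grid([p.doc_id for p in small_pairs], ["mock_a", "mock_b"], ["50", "100", "None"])
    return run_summarization(small_pairs, mock_summarizer(), grid)


def make_record(text, doc_id="d1", gender="female", model="m", level="50"):
    return SummaryRecord(doc_id, gender, model, level, text)
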