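import pytest

from esmo_mcbs import load_corpus


@pytest.fixture(scope="session")
def corpus_entries():
    return load_corpus()


@pytest.fixture(scope="session")
def corpus_records(corpus_entries):
    return [e.record for e in corpus_entries]


@pytest.fixture(scope="session")
def records_by_id(corpus_records):
    return {r.trial_id: r for r in corpus_records}
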