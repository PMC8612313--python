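import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_doc(message_id, tokens):
    from rumorgroups.corpus_io import TokenizedDoc

    return TokenizedDoc(message_id=str(message_id), tokens=tuple(tokens))


@pytest.fixture
def doc_factory():
    return make_doc


@pytest.fixture(scope="session")
def keywords():
    from rumorgroups.lexicons import load_keywords

    return load_keywords()


@pytest.fixture(scope="session")
def script_lexicon():
    from rumorgroups.lexicons import load_script_lexicon

    return load_script_lexicon()


def random_token_docs(rng, n_docs, vocab=30, min_len=2, max_len=8):
    """Random small documents over a shared vocabulary (ties likely)."""
    docs = []
    for i in range(n_docs):
        size = rng.integers(min_len, max_len + 1)
        toks = rng.choice(vocab, size=size, replace=False)
        docs.append(make_doc(f"d{i}", [f"t{t}" for t in toks]))
    return docs


@pytest.fixture
def random_docs():
    return random_token_docs
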