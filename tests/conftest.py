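import pytest

from wconet.preprocess import (
    CleanSentence,
    Corpus,
    DictionaryLemmatizer,
    Document,
    FilterConfig,
)


@pytest.fixture(scope="session")
def sample_lexicon() -> DictionaryLemmatizer:
    """The packaged toy Italian lexicon."""
    from importlib import resources

    path = resources.files("wconet.data") / "lexicon_it_sample.tsv"
    with resources.as_file(path) as p:
        return DictionaryLemmatizer.from_tsv(p)


@pytest.fixture
def default_filter() -> FilterConfig:
    return FilterConfig(stoplist=frozenset({"il", "la", "di", "che", "non"}))


def make_corpus(sentence_lists: list[list[list[str]]]) -> Corpus:
    """Corpus from nested lists: documents -> sentences -> lemma tokens."""
    docs = []
    for i, sentences in enumerate(sentence_lists):
        docs.append(
            Document(
                respondent_id=f"D{i}",
                raw_word_count=sum(len(s) for s in sentences),
                n_raw_sentences=len(sentences),
                sentences=[CleanSentence(tuple(s)) for s in sentences],
            )
        )
    return Corpus(docs)


@pytest.fixture
def tiny_corpus() -> Corpus:
    """5 sentences over 3 words with known co-occurrence structure."""
    return make_corpus(
        [
            [["swab", "swab", "result"], ["swab"]],
            [["result", "mask"], ["mask", "swab"]],
            [["mask"]],
        ]
    )
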