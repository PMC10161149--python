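"""Ingestion, tokenization, cleaning filters and reporting arithmetic."""

import math

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wconet.preprocess import (
    POS,
    AnnotatedToken,
    CleanSentence,
    Corpus,
    CorpusStats,
    DictionaryLemmatizer,
    Document,
    FilterConfig,
    RawResponse,
    annotate,
    clean_tokens,
    corpus_stats,
    filter_short_responses,
    preprocess_corpus,
    read_corpus_jsonl,
    read_responses,
    read_token_annotations,
    round_half_away,
    sample_characteristics,
    split_sentences,
    tokenize_words,
    write_corpus_jsonl,
    write_responses,
)


# --------------------------------------------------------------------------
# ingestion


class TestReadResponses:
    def test_roundtrip_with_metadata(self, tmp_path):
        responses = [
            RawResponse("a", "more staff please", {"mode_of_birth": "caesarean"}),
            RawResponse("b", "", {"mode_of_birth": "vaginal"}),
            RawResponse("c", "più ostetriche", {"mode_of_birth": "vaginal"}),
        ]
        path = tmp_path / "r.csv"
        write_responses(responses, path)
        back = read_responses(path)
        assert [r.respondent_id for r in back] == ["a", "b", "c"]
        assert back[1].text == ""  # empty cell is not an error
        assert all(r.metadata["mode_of_birth"] == o.metadata["mode_of_birth"]
                   for r, o in zip(back, responses))

    def test_duplicate_id_is_error(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("respondent_id,text\nx,a\nx,b\n")
        with pytest.raises(ValueError, match="x"):
            read_responses(path)

    def test_missing_column_and_file(self, tmp_path):
        path = tmp_path / "r.csv"
        path.write_text("respondent_id,answer\n1,hello\n")
        with pytest.raises(KeyError, match="text"):
            read_responses(path)
        with pytest.raises(FileNotFoundError):
            read_responses(tmp_path / "nope.csv")


class TestTokenization:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("", []),
            ("More staff. Better food!", ["More staff", "Better food"]),
            ("one sentence with no terminator", ["one sentence with no terminator"]),
            ("a;b\nc?!d...", ["a", "b", "c", "d"]),
        ],
    )
    def test_split_sentences(self, text, expected):
        assert split_sentences(text) == expected

    @pytest.mark.parametrize(
        "sentence, tokens",
        [
            ("no suggestion", ["no", "suggestion"]),
            ("", []),
            ("COVID-19 swab,", ["COVID", "swab"]),
            ("l'ostetrica è brava", ["l'ostetrica", "è", "brava"]),
            ("12 34", []),
        ],
    )
    def test_tokenize_words(self, sentence, tokens):
        assert tokenize_words(sentence) == tokens

    @settings(derandomize=True, max_examples=50)
    @given(st.text(max_size=200))
    def test_sentence_content_conserved(self, text):
        """Concatenating sentences reproduces the non-delimiter content."""
        joined = "".join(split_sentences(text))
        stripped = "".join(ch for ch in text if ch not in ".!?;\n")
        # splitting also strips whitespace at fragment boundaries, so
        # compare modulo all whitespace
        assert "".join(joined.split()) == "".join(stripped.split())


# --------------------------------------------------------------------------
# annotation


class TestAnnotate:
    def test_lexicon_lookup(self):
        lem = DictionaryLemmatizer({"infermiere": ("infermiere", POS.NOUN)})
        (tok,) = annotate(["infermiere"], lem)
        assert (tok.lemma, tok.pos) == ("infermiere", POS.NOUN)

    def test_unknown_fallback(self):
        (tok,) = annotate(["Xyzq"], DictionaryLemmatizer())
        assert (tok.lemma, tok.pos) == ("xyzq", POS.OTHER)

    def test_plural_maps_to_singular(self, sample_lexicon):
        (tok,) = annotate(["tamponi"], sample_lexicon)
        assert tok.lemma == "tampone"
        assert tok.pos == POS.NOUN


class TestTokenAnnotations:
    def test_fixture_file(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("tamponi\tNOUN\ttampone\n.\tSENT\t.\n")
        sentences = read_token_annotations(path)
        assert len(sentences) == 1
        assert sentences[0] == [AnnotatedToken("tamponi", "tampone", POS.NOUN)]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("")
        assert read_token_annotations(path) == []

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("ok\tNOUN\tok\nbad\tNOUN\n")
        with pytest.raises(ValueError, match=":2"):
            read_token_annotations(path)

    def test_unmapped_tag_names_tag(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text("x\tWEIRD\tx\n")
        with pytest.raises(ValueError, match="WEIRD"):
            read_token_annotations(path)


# --------------------------------------------------------------------------
# cleaning filters


def _doc(n_words: int, rid: str = "d") -> Document:
    return Document(rid, n_words, 1, [CleanSentence(("w",) * n_words)])


class TestShortAnswerFilter:
    def test_strict_boundary(self):
        docs = [_doc(3, "three"), _doc(4, "four")]
        filter_short_responses(docs, 4)
        assert docs[0].excluded == "short-answer"
        assert docs[1].excluded is None  # exactly min_words is retained

    def test_hand_counted_set(self):
        docs = [_doc(n, str(n)) for n in (2, 3, 4, 7, 10)]
        _, n_excluded = filter_short_responses(docs, 4)
        assert n_excluded == 2
        assert sum(d.excluded is None for d in docs) == 3

    def test_min_words_zero_is_config_error(self):
        with pytest.raises(ValueError, match="min_words"):
            filter_short_responses([_doc(1)], 0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.integers(0, 12), max_size=20), st.integers(1, 6))
    def test_bookkeeping(self, counts, min_words):
        docs = [_doc(n, f"d{i}") for i, n in enumerate(counts)]
        retained, n_excluded = filter_short_responses(docs, min_words)
        assert len(retained) == len(counts)
        assert sum(d.excluded == "short-answer" for d in docs) == n_excluded
        assert sum(d.excluded is None for d in docs) + n_excluded == len(counts)


class TestCleanTokens:
    def test_stopword_removed(self, default_filter):
        toks = [
            AnnotatedToken("il", "il", POS.DET),
            AnnotatedToken("tampone", "tampone", POS.NOUN),
        ]
        assert clean_tokens(toks, default_filter).tokens == ("tampone",)

    def test_all_filtered_gives_empty(self, default_filter):
        toks = [AnnotatedToken("il", "il", POS.DET)]
        assert clean_tokens(toks, default_filter).tokens == ()

    def test_pos_classes_filtered(self, default_filter):
        toks = [
            AnnotatedToken("sempre", "sempre", POS.ADV),
            AnnotatedToken("due", "due", POS.NUM),
            AnnotatedToken("latte", "latte", POS.NOUN),
            AnnotatedToken("padre", "padre", POS.NOUN),
        ]
        assert clean_tokens(toks, default_filter).tokens == ("latte", "padre")

    def test_drop_pattern(self, default_filter):
        toks = [
            AnnotatedToken("e", "e", POS.OTHER),          # length 1
            AnnotatedToken("ther's", "ther's", POS.OTHER),  # non-letter char
            AnnotatedToken("min", "min", POS.OTHER),
        ]
        assert clean_tokens(toks, default_filter).tokens == ("min",)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from(["il", "latte", "x", "padre", "sempre"])))
    def test_vocabulary_shrinks(self, surfaces):
        config = FilterConfig(stoplist=frozenset({"il"}))
        toks = [AnnotatedToken(s, s, POS.NOUN) for s in surfaces]
        cleaned = clean_tokens(toks, config)
        assert set(cleaned.tokens) <= {t.lemma for t in toks}


class TestPreprocessCorpus:
    def test_end_to_end_document(self, sample_lexicon):
        responses = [
            RawResponse("a", "I tamponi sempre; il latte molto buono.", {}),
            RawResponse("b", "no grazie", {}),
        ]
        config = FilterConfig(stoplist=frozenset({"il", "i", "buono"}))
        corpus = preprocess_corpus(responses, sample_lexicon, config)
        doc_a, doc_b = corpus.documents
        assert doc_b.excluded == "short-answer"
        assert doc_a.excluded is None
        # "I" dropped (length 1 + stoplist), "sempre"/"molto" adverbs dropped,
        # "tamponi" lemmatized, "buono" stop-listed
        assert [s.tokens for s in doc_a.sentences] == [("tampone",), ("latte",)]

    def test_empty_after_cleaning_flag(self, sample_lexicon):
        responses = [RawResponse("a", "sempre molto subito sempre.", {})]
        corpus = preprocess_corpus(responses, sample_lexicon, FilterConfig())
        assert corpus.documents[0].excluded == "empty-after-cleaning"
        # still a retained respondent for statistics
        assert corpus_stats(corpus).n_respondents_retained == 1
        # but contributes no sentences to the matrix
        assert corpus.clean_sentences() == []

    def test_corpus_jsonl_roundtrip(self, tmp_path, sample_lexicon):
        responses = [
            RawResponse("a", "il tampone covid e la mascherina covid.", {}),
            RawResponse("b", "no", {}),
        ]
        corpus = preprocess_corpus(
            responses, sample_lexicon, FilterConfig(stoplist=frozenset({"il", "la"}))
        )
        path = tmp_path / "c.jsonl"
        write_corpus_jsonl(corpus, path)
        back = read_corpus_jsonl(path)
        assert back.documents == corpus.documents


# --------------------------------------------------------------------------
# reporting


class TestRounding:
    @pytest.mark.parametrize(
        "x, nd, expected",
        [(0.25, 1, 0.3), (-0.25, 1, -0.3), (9.45, 1, 9.5), (1.5, 0, 2.0),
         (2.5, 0, 3.0), (43.6318, 1, 43.6)],
    )
    def test_half_away_from_zero(self, x, nd, expected):
        assert round_half_away(x, nd) == expected


class TestCorpusStats:
    def test_empty_corpus(self):
        stats = corpus_stats(Corpus([]))
        assert stats.n_words == 0 and stats.n_sentences == 0
        assert stats.mean_words_per_respondent is None

    def test_two_document_arithmetic(self):
        docs = [
            Document("a", 10, 1, [CleanSentence(("x",))]),
            Document("b", 30, 3, [CleanSentence(("x",))] * 3),
        ]
        stats = corpus_stats(Corpus(docs))
        assert stats.mean_words_per_respondent == 20
        assert stats.mean_sentences_per_respondent == 2

    def test_sentence_mean_from_printed_totals(self):
        stats = CorpusStats.from_totals(79204, 3833, 2010)
        assert stats.mean_sentences_per_respondent == 2


class TestSampleCharacteristics:
    def test_reference_age_band_percent(self):
        df = pd.DataFrame({"age": ["31-35"] * 877 + ["other"] * (2010 - 877)})
        table = sample_characteristics(df, ["age"])
        row = table[table.category == "31-35"].iloc[0]
        assert row["count"] == 877
        assert row["percent"] == 43.6

    def test_caesarean_percent(self):
        df = pd.DataFrame({"mode": ["caesarean"] * 596 + ["vaginal"] * 1414})
        table = sample_characteristics(df, ["mode"])
        assert table[table.category == "caesarean"].iloc[0]["percent"] == 29.7

    def test_single_category_is_100(self):
        df = pd.DataFrame({"v": ["only"] * 7})
        assert sample_characteristics(df, ["v"]).iloc[0]["percent"] == 100.0

    def test_unknown_variable(self):
        with pytest.raises(KeyError, match="nope"):
            sample_characteristics(pd.DataFrame({"v": ["a"]}), ["nope"])

    def test_multi_select_exempt_from_sum_rule(self):
        df = pd.DataFrame({"m1": [1, 1, 0], "m2": [1, 1, 1]})
        table = sample_characteristics(df, [], multi_select={"prov": ["m1", "m2"]})
        assert table["count"].tolist() == [2, 3]  # sums to more than n=3

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from("abc"), min_size=1, max_size=60))
    def test_percent_closure(self, values):
        """Unrounded single-choice percents sum to exactly 100."""
        df = pd.DataFrame({"v": values})
        table = sample_characteristics(df, ["v"])
        unrounded = sum(100.0 * c / len(values) for c in table["count"])
        assert math.isclose(unrounded, 100.0, abs_tol=1e-9)
        assert table["count"].sum() == len(values)
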