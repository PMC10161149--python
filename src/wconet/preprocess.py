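"""Survey-response preprocessing: ingestion, tokenization, lemma/POS cleaning.

Free-text answers are split into sentences and word tokens, each token is
mapped to its lemma and part of speech (via a pluggable lemmatizer or an
external tagger's annotation file), and a sequence of cleaning filters is
applied: short non-informative answers (fewer than ``min_words`` raw words)
are excluded, stop-words and uninformative grammatical classes (adverbs,
proper nouns, determiners/indefinite adjectives, numerals, symbols) are
removed, and malformed tokens are dropped. The result is a corpus of
documents whose sentences contain only content lemmas, plus corpus-level
statistics and a sample-characteristics table.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "POS",
    "RawResponse",
    "AnnotatedToken",
    "CleanSentence",
    "Document",
    "FilterConfig",
    "Corpus",
    "CorpusStats",
    "Lemmatizer",
    "DictionaryLemmatizer",
    "read_responses",
    "split_sentences",
    "tokenize_words",
    "annotate",
    "read_token_annotations",
    "read_stoplist",
    "filter_short_responses",
    "clean_tokens",
    "preprocess_corpus",
    "corpus_stats",
    "sample_characteristics",
    "round_half_away",
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_responses",
]


class POS(str, Enum):
    """Closed tagset used throughout the pipeline.

    External tagsets (e.g. a TreeTagger-style tagger's) are mapped onto this
    set when annotation files are read.
    """

    NOUN = "noun"
    VERB = "verb"
    ADJ = "adjective"
    ADV = "adverb"
    PROPN = "proper-noun"
    DET = "determiner"  # determiners and indefinite adjectives
    NUM = "numeral"
    PUNCT = "punctuation"
    OTHER = "other"


#: POS classes removed during cleaning by default.
DEFAULT_EXCLUDED_POS = frozenset({POS.ADV, POS.PROPN, POS.DET, POS.NUM, POS.PUNCT})


@dataclass(frozen=True)
class RawResponse:
    respondent_id: str
    text: str
    metadata: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class AnnotatedToken:
    surface: str
    lemma: str
    pos: POS


@dataclass(frozen=True)
class CleanSentence:
    tokens: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass
class Document:
    """One respondent's answer after preprocessing.

    ``excluded`` is ``None`` for analysable documents, ``"short-answer"``
    when the raw word count fell below the minimum, and
    ``"empty-after-cleaning"`` when every sentence lost all its tokens.
    Short-answer documents contribute no sentences downstream and do not
    count as retained respondents; empty-after-cleaning documents count as
    retained respondents for corpus statistics but contribute no rows to the
    occurrence matrix.
    """

    respondent_id: str
    raw_word_count: int
    n_raw_sentences: int
    sentences: list[CleanSentence]
    excluded: str | None = None

    @property
    def is_short(self) -> bool:
        return self.excluded == "short-answer"


@dataclass
class FilterConfig:
    min_words: int = 4
    stoplist: frozenset[str] = frozenset()
    excluded_pos: frozenset[POS] = DEFAULT_EXCLUDED_POS
    drop_length_1: bool = True
    drop_nonletter: bool = True

    def __post_init__(self) -> None:
        if self.min_words < 1:
            raise ValueError(f"min_words must be >= 1, got {self.min_words}")
        self.stoplist = frozenset(self.stoplist)
        self.excluded_pos = frozenset(POS(p) for p in self.excluded_pos)

    def drops(self, lemma: str) -> bool:
        """Drop-pattern rule for truncated/irregular forms."""
        if self.drop_length_1 and len(lemma) <= 1:
            return True
        if self.drop_nonletter and not lemma.isalpha():
            return True
        return False


@dataclass
class Corpus:
    documents: list[Document]

    @property
    def retained(self) -> list[Document]:
        return [d for d in self.documents if not d.is_short]

    def clean_sentences(self) -> list[tuple[str, int, CleanSentence]]:
        """Non-empty clean sentences over retained documents.

        Returns (respondent_id, sentence ordinal within document, sentence).
        """
        out = []
        for doc in self.retained:
            for i, sent in enumerate(doc.sentences):
                if len(sent) > 0:
                    out.append((doc.respondent_id, i, sent))
        return out


@dataclass(frozen=True)
class CorpusStats:
    n_respondents_total: int
    n_respondents_retained: int
    n_words: int
    n_sentences: int
    mean_words_per_respondent: int | None
    mean_sentences_per_respondent: int | None

    @classmethod
    def from_totals(
        cls,
        n_words: int,
        n_sentences: int,
        n_respondents_retained: int,
        n_respondents_total: int | None = None,
    ) -> "CorpusStats":
        """Statistics from pre-computed totals (means rounded to nearest
        integer, half away from zero)."""
        if n_respondents_retained == 0:
            mw = ms = None
        else:
            mw = int(round_half_away(n_words / n_respondents_retained, 0))
            ms = int(round_half_away(n_sentences / n_respondents_retained, 0))
        return cls(
            n_respondents_total=(
                n_respondents_total
                if n_respondents_total is not None
                else n_respondents_retained
            ),
            n_respondents_retained=n_respondents_retained,
            n_words=n_words,
            n_sentences=n_sentences,
            mean_words_per_respondent=mw,
            mean_sentences_per_respondent=ms,
        )


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the reporting convention; Python's
    built-in ``round`` is half-to-even)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# --------------------------------------------------------------------------
# Ingestion


def read_responses(
    path: str | Path,
    id_col: str = "respondent_id",
    text_col: str = "text",
    metadata_cols: Sequence[str] | None = None,
    sep: str = ",",
) -> list[RawResponse]:
    """Read survey responses from a delimited UTF-8 text file.

    One row per respondent; ``metadata_cols=None`` carries through every
    column other than the id and text columns. Empty text cells are kept as
    empty strings. Duplicate respondent ids are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, encoding="utf-8")
    for col in (id_col, text_col):
        if col not in df.columns:
            raise KeyError(f"column {col!r} not found in {path.name}")
    if metadata_cols is None:
        metadata_cols = [c for c in df.columns if c not in (id_col, text_col)]
    else:
        missing = [c for c in metadata_cols if c not in df.columns]
        if missing:
            raise KeyError(f"metadata columns not found: {missing}")
    dupes = df[id_col][df[id_col].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate respondent_id: {dupes.iloc[0]!r}")
    responses = []
    for _, row in df.iterrows():
        meta = {c: row[c] for c in metadata_cols}
        responses.append(RawResponse(row[id_col], row[text_col], meta))
    return responses


def write_responses(responses: Iterable[RawResponse], path: str | Path) -> None:
    """Write responses as CSV, inverse of :func:`read_responses`."""
    responses = list(responses)
    meta_cols: list[str] = []
    for r in responses:
        for k in r.metadata:
            if k not in meta_cols:
                meta_cols.append(k)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["respondent_id", "text", *meta_cols])
        for r in responses:
            writer.writerow(
                [r.respondent_id, r.text, *(r.metadata.get(c, "") for c in meta_cols)]
            )


# --------------------------------------------------------------------------
# Tokenization

_SENTENCE_DELIMS = re.compile(r"[.!?;\n]+")
# Maximal runs of Unicode letters, optionally joined by internal apostrophes
# (straight or typographic).
_WORD = re.compile(r"[^\W\d_]+(?:[’'][^\W\d_]+)*", re.UNICODE)


def split_sentences(text: str) -> list[str]:
    """Split on ".", "!", "?", ";" and newlines; consecutive delimiters
    collapse; empty fragments are dropped."""
    return [s.strip() for s in _SENTENCE_DELIMS.split(text) if s.strip()]


def tokenize_words(sentence: str) -> list[str]:
    """Word tokens: maximal letter runs with internal apostrophes.

    Digits, punctuation and symbols act as separators, so "COVID-19" yields
    the single token "COVID". The token count is the raw word count used by
    the short-answer filter.
    """
    return _WORD.findall(sentence)


# --------------------------------------------------------------------------
# Lemmatization


class Lemmatizer(Protocol):
    def lookup(self, surface: str) -> tuple[str, POS] | None:
        """Return (lemma, pos) for a surface form, or None if unknown."""
        ...


class DictionaryLemmatizer:
    """Lexicon-backed lemmatizer (surface -> lemma, POS), case-insensitive.

    The lexicon file is TSV with columns surface, lemma, pos (pos values
    from the closed tagset). Unknown surfaces are handled by the caller
    (:func:`annotate` falls back to lemma = lowercased surface, pos=other).
    """

    def __init__(self, entries: Mapping[str, tuple[str, POS]] | None = None):
        self._entries: dict[str, tuple[str, POS]] = {
            k.lower(): (v[0].lower(), POS(v[1])) for k, v in (entries or {}).items()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DictionaryLemmatizer":
        entries: dict[str, tuple[str, POS]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 tab-separated columns, "
                        f"got {len(parts)}"
                    )
                surface, lemma, pos = parts
                entries[surface.lower()] = (lemma.lower(), POS(pos))
        return cls(entries)

    def lookup(self, surface: str) -> tuple[str, POS] | None:
        return self._entries.get(surface.lower())

    def __len__(self) -> int:
        return len(self._entries)


def annotate(tokens: Sequence[str], lemmatizer: Lemmatizer) -> list[AnnotatedToken]:
    """Annotate surface tokens with lemma and POS, order preserved.

    Unknown surfaces degrade gracefully to (lowercased surface, other).
    """
    out = []
    for tok in tokens:
        hit = lemmatizer.lookup(tok)
        if hit is None:
            logger.debug("unknown surface %r; falling back to identity lemma", tok)
            out.append(AnnotatedToken(tok, tok.lower(), POS.OTHER))
        else:
            lemma, pos = hit
            out.append(AnnotatedToken(tok, lemma, pos))
    return out


#: Default mapping from a TreeTagger-style external tagset onto the closed set.
DEFAULT_TAG_MAP: dict[str, POS] = {
    "NOUN": POS.NOUN, "NOM": POS.NOUN, "NN": POS.NOUN,
    "VERB": POS.VERB, "VER": POS.VERB,
    "ADJ": POS.ADJ,
    "ADV": POS.ADV,
    "NPR": POS.PROPN, "PROPN": POS.PROPN,
    "DET": POS.DET, "PRO_INDEF": POS.DET, "DET_INDEF": POS.DET,
    "NUM": POS.NUM,
    "PUN": POS.PUNCT, "PON": POS.PUNCT, "SYM": POS.PUNCT,
    "PRE": POS.OTHER, "CON": POS.OTHER, "PRO": POS.OTHER, "INT": POS.OTHER,
    "AUX": POS.VERB,
}

SENTENCE_BOUNDARY_TAG = "SENT"


def read_token_annotations(
    path: str | Path,
    tag_map: Mapping[str, POS] | None = None,
    boundary_tag: str = SENTENCE_BOUNDARY_TAG,
) -> list[list[AnnotatedToken]]:
    """Read an external tagger's token-per-line TSV (token, tag, lemma).

    A line whose tag equals ``boundary_tag`` closes the current sentence.
    The external tagset is mapped onto the closed tagset through
    ``tag_map``; an unmapped tag is an error naming the tag.
    """
    tag_map = dict(DEFAULT_TAG_MAP if tag_map is None else tag_map)
    sentences: list[list[AnnotatedToken]] = []
    current: list[AnnotatedToken] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            token, tag, lemma = parts
            if tag == boundary_tag:
                if current:
                    sentences.append(current)
                    current = []
                continue
            if tag not in tag_map:
                raise ValueError(f"{path}:{lineno}: unmapped POS tag {tag!r}")
            current.append(AnnotatedToken(token, lemma.lower(), tag_map[tag]))
    if current:
        sentences.append(current)
    return sentences


def read_stoplist(path: str | Path) -> frozenset[str]:
    """One lemma per line; blank lines and '#' comments ignored."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip().lower()
            for line in fh
            if line.strip() and not line.startswith("#")
        )


# --------------------------------------------------------------------------
# Cleaning


def clean_tokens(
    annotated: Sequence[AnnotatedToken], config: FilterConfig
) -> CleanSentence:
    """Apply stop-word, POS-class and drop-pattern filters; order preserved."""
    kept = [
        t.lemma
        for t in annotated
        if t.lemma not in config.stoplist
        and t.pos not in config.excluded_pos
        and not config.drops(t.lemma)
    ]
    return CleanSentence(tuple(kept))


def filter_short_responses(
    documents: Sequence[Document], min_words: int
) -> tuple[list[Document], int]:
    """Mark documents with fewer than ``min_words`` raw words as excluded.

    The boundary is strict: exactly ``min_words`` words is retained.
    Returns (all documents with exclusion applied, number excluded).
    """
    if min_words < 1:
        raise ValueError(f"min_words must be >= 1, got {min_words}")
    n_excluded = 0
    for doc in documents:
        if doc.raw_word_count < min_words:
            doc.excluded = "short-answer"
            doc.sentences = []
            n_excluded += 1
    return list(documents), n_excluded


def preprocess_corpus(
    responses: Sequence[RawResponse],
    lemmatizer: Lemmatizer,
    config: FilterConfig,
) -> Corpus:
    """Full preprocessing of raw responses into an analysis-ready corpus.

    Order of steps mirrors the screening procedure: sentence + word
    tokenization, short-answer exclusion on the raw word count, then
    lemma/POS annotation and token cleaning on retained documents.
    """
    documents: list[Document] = []
    for resp in responses:
        raw_sentences = split_sentences(resp.text)
        token_lists = [tokenize_words(s) for s in raw_sentences]
        raw_count = sum(len(t) for t in token_lists)
        doc = Document(
            respondent_id=resp.respondent_id,
            raw_word_count=raw_count,
            n_raw_sentences=len(raw_sentences),
            sentences=[],
        )
        if raw_count >= config.min_words:
            doc.sentences = [
                clean_tokens(annotate(toks, lemmatizer), config)
                for toks in token_lists
            ]
            if doc.sentences and all(len(s) == 0 for s in doc.sentences):
                doc.excluded = "empty-after-cleaning"
        documents.append(doc)
    filter_short_responses(documents, config.min_words)
    return Corpus(documents)


# --------------------------------------------------------------------------
# Statistics


def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Corpus totals and per-respondent means over retained respondents.

    Retained = not excluded by the short-answer filter (documents that
    emptied during cleaning still count as respondents). Word totals are raw
    word-token counts; sentence totals count sentence-tokenized sentences.
    Means are rounded to the nearest integer, half away from zero; with zero
    retained respondents the means are None.
    """
    retained = corpus.retained
    n_words = sum(d.raw_word_count for d in retained)
    n_sentences = sum(d.n_raw_sentences for d in retained)
    return CorpusStats.from_totals(
        n_words=n_words,
        n_sentences=n_sentences,
        n_respondents_retained=len(retained),
        n_respondents_total=len(corpus.documents),
    )


def sample_characteristics(
    metadata: pd.DataFrame,
    variables: Sequence[str],
    n: int | None = None,
    multi_select: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Per-category counts and percentages of the analysed sample.

    ``variables`` are single-choice categorical columns: counts sum to the
    denominator ``n`` (default: number of rows). ``multi_select`` maps a
    display name to 0/1 indicator columns whose counts need not sum to n.
    Percent = 100*count/n rounded to one decimal, half away from zero.
    """
    if n is None:
        n = len(metadata)
    rows = []
    for var in variables:
        if var not in metadata.columns:
            raise KeyError(f"unknown variable {var!r}")
        counts = metadata[var].value_counts()
        for category in sorted(counts.index.astype(str)):
            count = int(counts[category])
            rows.append(
                (var, category, count, round_half_away(100.0 * count / n, 1))
            )
    for name, cols in (multi_select or {}).items():
        for col in cols:
            if col not in metadata.columns:
                raise KeyError(f"unknown variable {col!r}")
            count = int(metadata[col].astype(int).sum())
            rows.append(
                (name, col, count, round_half_away(100.0 * count / n, 1))
            )
    return pd.DataFrame(rows, columns=["variable", "category", "count", "percent"])


# --------------------------------------------------------------------------
# Corpus serialization (JSON-lines, one document per line)


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus.documents:
            fh.write(
                json.dumps(
                    {
                        "respondent_id": doc.respondent_id,
                        "raw_word_count": doc.raw_word_count,
                        "n_raw_sentences": doc.n_raw_sentences,
                        "excluded": doc.excluded,
                        "sentences": [list(s.tokens) for s in doc.sentences],
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_corpus_jsonl(path: str | Path) -> Corpus:
    documents = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            documents.append(
                Document(
                    respondent_id=obj["respondent_id"],
                    raw_word_count=obj["raw_word_count"],
                    n_raw_sentences=obj["n_raw_sentences"],
                    sentences=[CleanSentence(tuple(s)) for s in obj["sentences"]],
                    excluded=obj["excluded"],
                )
            )
    return Corpus(documents)
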