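"""Planted-topic synthetic corpora with the structure the pipeline assumes.

The generator emulates an open-ended maternal-survey corpus: ~2000
respondents writing 1–3 sentences (mean 2) of ~20 raw words each (mean ~40
words per respondent), with a small fraction of short non-informative
answers ("no", "niente da aggiungere") that the <4-word filter removes, and
function words (stop-words) interleaved among content words. Content words
come either from one of K disjoint planted topic vocabularies (a topical
sentence carries at least two words of its topic, creating within-sentence
co-occurrence signal) or from a larger background vocabulary whose words
appear independently of each other and of the topics. The planted
topic→word assignment is returned as ground truth, so cluster recovery can
be scored with the adjusted Rand index.

Words are letter-only pseudo-lemmas (consonant–vowel syllables), so they
pass the tokenizer and drop-pattern untouched; no attempt is made to model
real grammar or the study's actual theme content.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .network import Cluster
from .preprocess import RawResponse, read_stoplist

__all__ = [
    "GeneratorParams",
    "PlantedTruth",
    "RecoveryScore",
    "generate_corpus",
    "generate_metadata",
    "evaluate_recovery",
    "make_vocabulary",
    "default_stopwords",
    "REFERENCE_SAMPLE_COUNTS",
    "REFERENCE_MULTI_SELECT_COUNTS",
    "SHORT_ANSWERS",
]

#: Short non-informative answers (all under four words).
SHORT_ANSWERS = (
    "no",
    "nessun suggerimento",
    "niente da aggiungere",
    "no grazie",
    "tutto bene",
)

#: Reference per-category counts of an Italian maternal-survey sample
#: (n = 2010), used with exact-count metadata generation. Only variables
#: whose counts are internally consistent (sum to n) are included.
REFERENCE_SAMPLE_COUNTS: dict[str, dict[str, int]] = {
    "maternal_age": {
        "18-24": 40, "25-30": 407, "31-35": 877, "36-39": 496, ">=40": 190,
    },
    "parity": {"1": 1460, ">1": 550},
    "same_country_of_birth": {"yes": 1916, "no": 94},
    "mode_of_birth": {
        "vaginal_spontaneous": 1245,
        "instrumental_vaginal": 169,
        "caesarean": 596,
    },
    "type_of_facility": {"public": 1880, "private": 130},
}

#: Multi-select indicators for the same reference sample (counts out of
#: n = 2010; a respondent may tick several).
REFERENCE_MULTI_SELECT_COUNTS: dict[str, int] = {
    "provider_midwife": 1733,
    "provider_nurse": 504,
    "provider_student": 103,
    "provider_registrar": 314,
    "provider_obgyn": 1128,
    "provider_unknown": 213,
    "newborn_nicu": 184,
    "multiple_birth": 25,
    "mother_icu": 5,
}


def default_stopwords() -> frozenset[str]:
    """Packaged Italian function-word stoplist."""
    path = resources.files("wconet.data") / "stopwords_it.txt"
    with resources.as_file(path) as p:
        return read_stoplist(p)


_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]


def make_vocabulary(n: int, avoid: frozenset[str] = frozenset()) -> list[str]:
    """Deterministic sequence of n distinct three-syllable pseudo-lemmas."""
    out: list[str] = []
    for s1, s2, s3 in itertools.product(_SYLLABLES, repeat=3):
        word = s1 + s2 + s3
        if word in avoid:
            continue
        out.append(word)
        if len(out) == n:
            return out
    raise ValueError(f"cannot build {n} distinct pseudo-lemmas")


@dataclass
class GeneratorParams:
    """Study conditions for corpus generation.

    Defaults emulate the target corpus scale: 2010 respondents, 1–3
    sentences each (mean 2.0), ~20 raw words per sentence (about 40% of
    them stop-words), ~6% short non-informative answers, and 8 planted
    topics of 9 words each over a 120-word background vocabulary, with 80%
    of sentences topical.
    """

    n_respondents: int = 2010
    n_topics: int = 8
    words_per_topic: int = 9
    background_size: int = 120
    sentence_count_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.50, 3: 0.25}
    )
    words_per_sentence_mean: float = 20.0
    p_topic_sentence: float = 0.8
    p_short: float = 0.062
    stop_rate: float = 0.4
    topic_word_fraction: float = 0.35  # of content slots in a topical sentence
    topic_vocabularies: list[list[str]] | None = None
    background_vocabulary: list[str] | None = None
    stopwords: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name in ("p_topic_sentence", "p_short", "stop_rate",
                     "topic_word_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_respondents < 1 or self.n_topics < 1 or self.words_per_topic < 1:
            raise ValueError("n_respondents, n_topics, words_per_topic must be >= 1")
        total_p = sum(self.sentence_count_dist.values())
        if abs(total_p - 1.0) > 1e-9:
            raise ValueError(f"sentence_count_dist sums to {total_p}, not 1")
        if any(k < 1 for k in self.sentence_count_dist):
            raise ValueError("sentence counts must be >= 1")
        if self.stopwords is None:
            self.stopwords = default_stopwords()
        if self.topic_vocabularies is None or self.background_vocabulary is None:
            pool = make_vocabulary(
                self.n_topics * self.words_per_topic + self.background_size,
                avoid=self.stopwords,
            )
            if self.topic_vocabularies is None:
                self.topic_vocabularies = [
                    pool[t * self.words_per_topic: (t + 1) * self.words_per_topic]
                    for t in range(self.n_topics)
                ]
            if self.background_vocabulary is None:
                self.background_vocabulary = pool[
                    self.n_topics * self.words_per_topic:
                    self.n_topics * self.words_per_topic + self.background_size
                ]
        sets = [frozenset(v) for v in self.topic_vocabularies]
        sets.append(frozenset(self.background_vocabulary))
        union = frozenset().union(*sets)
        if len(union) != sum(len(s) for s in sets):
            raise ValueError(
                "topic vocabularies must be pairwise disjoint and disjoint "
                "from the background vocabulary"
            )
        if union & self.stopwords:
            raise ValueError("vocabularies must be disjoint from stop-words")


@dataclass
class PlantedTruth:
    """Ground-truth topic assignment of a generated corpus."""

    topic_words: dict[int, frozenset[str]]
    #: (respondent_id, sentence ordinal) -> topic id, or None for background
    sentence_topics: dict[tuple[str, int], int | None]

    def word_topic(self) -> dict[str, int]:
        return {w: t for t, words in self.topic_words.items() for w in words}


@dataclass(frozen=True)
class RecoveryScore:
    ari: float | None
    exact_match: bool
    n_recovered_clusters: int
    n_unclustered_planted: int
    n_extra_words: int


def _sentence_words(
    rng: np.random.Generator, params: GeneratorParams, topic: int | None
) -> list[str]:
    n_total = int(np.clip(rng.poisson(params.words_per_sentence_mean), 5, 60))
    n_stop = int(round(params.stop_rate * n_total))
    n_content = n_total - n_stop
    background = params.background_vocabulary
    words: list[str] = []
    if topic is not None:
        vocab = params.topic_vocabularies[topic]
        k = int(rng.binomial(n_content, params.topic_word_fraction))
        k = max(2, min(k, n_content, len(vocab)))
        words.extend(rng.choice(vocab, size=k, replace=False).tolist())
        filler = background if background else vocab
        if n_content - k > 0:
            words.extend(rng.choice(filler, size=n_content - k).tolist())
    else:
        words.extend(rng.choice(background, size=n_content).tolist())
    if n_stop and params.stopwords:
        stop_pool = sorted(params.stopwords)
        words.extend(rng.choice(stop_pool, size=n_stop).tolist())
    order = rng.permutation(len(words))
    return [words[i] for i in order]


def generate_corpus(
    params: GeneratorParams, seed: int
) -> tuple[list[RawResponse], PlantedTruth]:
    """Generate respondent answers plus the planted ground truth.

    One sub-stream per respondent (seeded from the run seed and the
    respondent index), so the corpus is reproducible even under partial
    regeneration. A sentence is topical with probability
    ``p_topic_sentence`` (always, if there is no background vocabulary);
    topical sentences carry >= 2 distinct words of their topic.
    """
    counts = sorted(params.sentence_count_dist)
    probs = [params.sentence_count_dist[c] for c in counts]
    p_topic = params.p_topic_sentence if params.background_vocabulary else 1.0
    responses: list[RawResponse] = []
    sentence_topics: dict[tuple[str, int], int | None] = {}
    for i in range(params.n_respondents):
        rng = np.random.default_rng([seed, i])
        rid = f"R{i + 1:05d}"
        if rng.random() < params.p_short:
            responses.append(
                RawResponse(rid, SHORT_ANSWERS[i % len(SHORT_ANSWERS)], {})
            )
            continue
        n_sent = int(rng.choice(counts, p=probs))
        sentences = []
        for s in range(n_sent):
            topic = (
                int(rng.integers(params.n_topics))
                if rng.random() < p_topic
                else None
            )
            sentence_topics[(rid, s)] = topic
            sentences.append(" ".join(_sentence_words(rng, params, topic)))
        responses.append(RawResponse(rid, ". ".join(sentences) + ".", {}))
    truth = PlantedTruth(
        topic_words={
            t: frozenset(v) for t, v in enumerate(params.topic_vocabularies)
        },
        sentence_topics=sentence_topics,
    )
    return responses, truth


def generate_metadata(
    n: int,
    distributions: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    exact_counts: Mapping[str, Mapping[str, int]] | None = None,
    multi_select_counts: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Respondent metadata table with given categorical structure.

    ``distributions`` draws each single-choice variable i.i.d. from the
    given category probabilities (must sum to 1). ``exact_counts`` instead
    assigns exactly the given per-category counts (must sum to n), in a
    seeded random order. ``multi_select_counts`` adds 0/1 indicator columns
    with exactly the given number of ones.
    """
    rng = np.random.default_rng(seed)
    data: dict[str, object] = {
        "respondent_id": [f"R{i + 1:05d}" for i in range(n)]
    }
    for var, dist in (distributions or {}).items():
        cats = sorted(dist)
        p = np.array([dist[c] for c in cats], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"distribution for {var!r} sums to {p.sum()}, not 1")
        data[var] = rng.choice(cats, size=n, p=p).tolist()
    for var, cat_counts in (exact_counts or {}).items():
        total = sum(cat_counts.values())
        if total != n:
            raise ValueError(
                f"exact counts for {var!r} sum to {total}, expected n={n}"
            )
        col = [c for c in sorted(cat_counts) for _ in range(cat_counts[c])]
        data[var] = [col[i] for i in rng.permutation(n)]
    for var, count in (multi_select_counts or {}).items():
        if not 0 <= count <= n:
            raise ValueError(f"count for {var!r} must be in [0, n]")
        col = np.zeros(n, dtype=int)
        col[rng.choice(n, size=count, replace=False)] = 1
        data[var] = col.tolist()
    return pd.DataFrame(data)


def evaluate_recovery(
    clusters: Sequence[Cluster], truth: PlantedTruth
) -> RecoveryScore:
    """Score recovered word clusters against the planted topics.

    The adjusted Rand index is computed over words that are both planted
    and clustered; planted words missing from every cluster are reported
    separately (as are clustered non-planted words), rather than folded
    into the index. ``exact_match`` requires the recovered partition to
    equal the planted one word-for-word.
    """
    planted = truth.word_topic()
    recovered: dict[str, int] = {}
    for idx, c in enumerate(clusters):
        for w in c.members:
            recovered[w] = c.rank if c.rank is not None else idx
    common = sorted(set(planted) & set(recovered))
    if not common:
        return RecoveryScore(
            ari=None,
            exact_match=False,
            n_recovered_clusters=len(clusters),
            n_unclustered_planted=len(set(planted) - set(recovered)),
            n_extra_words=len(set(recovered) - set(planted)),
        )
    ari = float(
        adjusted_rand_score(
            [planted[w] for w in common], [recovered[w] for w in common]
        )
    )
    exact = {frozenset(c.members) for c in clusters} == set(
        truth.topic_words.values()
    )
    return RecoveryScore(
        ari=ari,
        exact_match=exact,
        n_recovered_clusters=len(clusters),
        n_unclustered_planted=len(set(planted) - set(recovered)),
        n_extra_words=len(set(recovered) - set(planted)),
    )
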