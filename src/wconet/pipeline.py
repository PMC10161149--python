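"""End-to-end orchestration: preprocess -> cooccurrence -> network -> plot.

A single declarative :class:`RunConfig` drives one reproducible run; every
stage writes its outputs under the run directory and the run closes with a
manifest (config snapshot, input digests, per-stage record counts, version,
timestamps) whose counts are mutually consistent by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import cooccurrence as co
from . import network as net
from . import preprocess as pp
from . import viz

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "RunManifest",
    "AnalysisResult",
    "validate_config",
    "run_pipeline",
    "analyze_corpus",
]


@dataclass
class RunConfig:
    input_path: str | None = None
    id_col: str = "respondent_id"
    text_col: str = "text"
    stoplist_path: str | None = None
    lexicon_path: str | None = None
    annotations_path: str | None = None
    translations_path: str | None = None
    labels_path: str | None = None
    min_words: int = 4
    min_sentence_freq: int = 5
    rho_min: float = 0.1
    binary: bool = False
    cluster_method: str = "components"
    seed: int = 1
    out_dir: str = "wconet_run"

    def to_json(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_json(cls, obj: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(obj) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))


def validate_config(config: RunConfig) -> list[str]:
    """Report every violated invariant with its field name (never raises)."""
    violations = []
    if config.min_words < 1:
        violations.append(f"min_words: must be >= 1, got {config.min_words}")
    if config.min_sentence_freq < 1:
        violations.append(
            f"min_sentence_freq: must be >= 1, got {config.min_sentence_freq}"
        )
    if not (-1.0 < config.rho_min <= 1.0):
        violations.append(f"rho_min: must be in (-1, 1], got {config.rho_min}")
    if config.cluster_method not in net.CLUSTER_METHODS:
        violations.append(
            f"cluster_method: {config.cluster_method!r} not in {net.CLUSTER_METHODS}"
        )
    if config.seed < 0:
        violations.append(f"seed: must be >= 0, got {config.seed}")
    for name in ("input_path", "stoplist_path", "lexicon_path",
                 "annotations_path", "translations_path", "labels_path"):
        value = getattr(config, name)
        if value is not None and not Path(value).exists():
            violations.append(f"{name}: file not found: {value}")
    return violations


@dataclass
class RunManifest:
    config: dict
    input_digests: dict[str, str]
    counts: dict[str, int]
    version: str = ""
    started_at: float = 0.0
    finished_at: float = 0.0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


@dataclass
class AnalysisResult:
    corpus: pp.Corpus
    stats: pp.CorpusStats
    matrix: co.OccurrenceMatrix
    candidates: list[co.EdgeCandidate]
    edges: co.EdgeList
    graph: object
    clusters: list[net.Cluster]
    summary: net.NetworkSummary


def analyze_corpus(
    corpus: pp.Corpus,
    min_sentence_freq: int = 5,
    rho_min: float = 0.1,
    binary: bool = False,
    cluster_method: str = "components",
) -> AnalysisResult:
    """Run the co-occurrence and network stages on a preprocessed corpus."""
    stats = pp.corpus_stats(corpus)
    matrix = co.build_occurrence_matrix(
        corpus, min_sentence_freq=min_sentence_freq, binary=binary
    )
    candidates = co.pairwise_cooccurrence(matrix)
    edges = co.threshold_edges(candidates, rho_min, n_sentences=matrix.n_sentences)
    graph = net.build_network(edges)
    clusters = net.rank_clusters(net.detect_clusters(graph, cluster_method))
    summary = net.network_summary(graph, clusters)
    return AnalysisResult(
        corpus, stats, matrix, candidates, edges, graph, clusters, summary
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, write all stage outputs, return the manifest.

    Raises on the first stage error, naming the stage.
    """
    from . import __version__

    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    if config.input_path is None:
        raise ValueError("invalid config: input_path is required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    started = time.time()
    digests = {
        name: _sha256(path)
        for name, path in (
            ("input", config.input_path),
            ("stoplist", config.stoplist_path),
            ("lexicon", config.lexicon_path),
            ("annotations", config.annotations_path),
            ("translations", config.translations_path),
        )
        if path is not None
    }

    # --- preprocess ---------------------------------------------------
    try:
        responses = pp.read_responses(
            config.input_path, id_col=config.id_col, text_col=config.text_col
        )
        stoplist = (
            pp.read_stoplist(config.stoplist_path)
            if config.stoplist_path
            else frozenset()
        )
        lemmatizer = (
            pp.DictionaryLemmatizer.from_tsv(config.lexicon_path)
            if config.lexicon_path
            else pp.DictionaryLemmatizer()
        )
        filt = pp.FilterConfig(min_words=config.min_words, stoplist=stoplist)
        corpus = pp.preprocess_corpus(responses, lemmatizer, filt)
        pp.write_corpus_jsonl(corpus, out_dir / "corpus.jsonl")
        stats = pp.corpus_stats(corpus)
        (out_dir / "corpus_stats.json").write_text(
            json.dumps(dataclasses.asdict(stats), indent=2), encoding="utf-8"
        )
    except Exception as exc:
        raise RuntimeError(f"stage preprocess failed: {exc}") from exc

    # --- cooccurrence -------------------------------------------------
    try:
        matrix = co.build_occurrence_matrix(
            corpus, min_sentence_freq=config.min_sentence_freq, binary=config.binary
        )
        co.write_occurrence_matrix(matrix, out_dir / "matrix")
        candidates = co.pairwise_cooccurrence(matrix)
        edges = co.threshold_edges(
            candidates, config.rho_min, n_sentences=matrix.n_sentences
        )
        co.write_edge_list(edges, out_dir / "edges.csv")
    except Exception as exc:
        raise RuntimeError(f"stage cooccurrence failed: {exc}") from exc

    # --- network ------------------------------------------------------
    try:
        graph = net.build_network(edges)
        clusters = net.rank_clusters(
            net.detect_clusters(graph, config.cluster_method)
        )
        summary = net.network_summary(graph, clusters)
        net.write_graphml(graph, clusters, out_dir / "network.graphml")
        net.write_cluster_membership(graph, clusters, out_dir / "clusters.csv")
        net.write_summary(summary, out_dir / "summary.json")
    except Exception as exc:
        raise RuntimeError(f"stage network failed: {exc}") from exc

    # --- plot ---------------------------------------------------------
    try:
        layout = viz.compute_layout(graph, clusters, seed=config.seed)
        translations = (
            viz.load_translations(config.translations_path)
            if config.translations_path
            else {}
        )
        style = viz.StyleSpec(rho_min=config.rho_min, translations=translations)
        labels = (
            net.load_cluster_labels(config.labels_path)
            if config.labels_path
            else None
        )
        viz.render_network(graph, clusters, layout, style, out_dir, labels)
    except Exception as exc:
        raise RuntimeError(f"stage plot failed: {exc}") from exc

    manifest = RunManifest(
        config=config.to_json(),
        input_digests=digests,
        counts={
            "respondents_in": stats.n_respondents_total,
            "respondents_retained": stats.n_respondents_retained,
            "sentences": matrix.n_sentences,
            "vocabulary": matrix.n_vocab,
            "candidates": len(candidates),
            "edges": len(edges),
            "nodes": graph.number_of_nodes(),
            "clusters": len(clusters),
        },
        version=__version__,
        started_at=started,
        finished_at=time.time(),
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
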