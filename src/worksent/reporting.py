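"""End-to-end orchestration and the report tables: cleaning counts, sentiment
proportions and intensity histogram, coherence-selected topic count with
per-topic polarity, term-stratified counts, and labeled-subset tables.

Every percentage in a report is recomputed from counts that are also present
in the report (half-up rounding at the printed precision: two decimals for
corpus-level shares, nearest integer for labeled/topic shares).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from ._rounding import round_half_up
from .corpus_io import LabeledTweet, RawTweet, read_labels, read_tweets
from .labeled import class_proportions, top_frequent_words
from .lexicon import opinion_lexicon
from .preprocessing import CleaningConfig, preprocess_corpus
from .sentiment import intensity_histogram, score_corpus, term_stratified_counts
from .topic_polarity import assign_all_topics, class_top_words, polarity_proportions
from .topics import build_bow, scan_topic_counts, select_optimal_k, top_words

logger = logging.getLogger(__name__)


def proportions(counts: Sequence[int], decimals: int = 2) -> list[float]:
    """Percentages 100*count/total with half-up rounding at ``decimals`` places.

    ``decimals=2`` matches corpus-level reporting; ``decimals=0`` the
    labeled-subset and topic-polarity reporting (returns ints).
    """
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    if total <= 0:
        raise ValueError("total count must be positive")
    return [round_half_up(100.0 * c / total, decimals) for c in counts]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs, module parameters, stage toggles, and seeds for a full run."""

    tweets: list[RawTweet] | None = None
    tweets_path: str | Path | None = None
    labeled: list[LabeledTweet] | None = None
    labels_path: str | Path | None = None
    eliminated_keywords: tuple[str, ...] = ()
    seed: int = 0
    k_min: int = 2
    k_max: int = 8
    coherence_tolerance: float = 0.005
    topic_top_n: int = 30
    class_top_n: int = 50
    labeled_table_n: int = 10
    term: str = "covid"
    do_sentiment: bool = True
    do_topics: bool = True
    do_labeled: bool = True
    out_dir: str | Path | None = None


@dataclass
class RunReport:
    """All stage outputs of one pipeline run, counts alongside every percentage."""

    manifest: dict = field(default_factory=dict)
    cleaning: dict = field(default_factory=dict)
    sentiment: dict | None = None
    topics: dict | None = None
    labeled: dict | None = None

    def as_dict(self) -> dict:
        return {
            "manifest": self.manifest,
            "cleaning": self.cleaning,
            "sentiment": self.sentiment,
            "topics": self.topics,
            "labeled": self.labeled,
        }

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)


def _load_inputs(config: PipelineConfig) -> tuple[list[RawTweet], list[LabeledTweet] | None]:
    tweets = config.tweets
    if tweets is None and config.tweets_path is not None:
        tweets, _ = read_tweets(config.tweets_path)
    if tweets is None:
        raise ValueError("config provides neither tweets nor tweets_path")
    labeled = config.labeled
    if labeled is None and config.labels_path is not None:
        labeled = read_labels(config.labels_path)
    return tweets, labeled


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute clean -> score -> topics -> topic polarity -> labeled analysis.

    Identical config and inputs yield identical reports; any stage failure
    aborts with the stage name, earlier sections retained in the raised error's
    partially filled report.
    """
    report = RunReport()
    report.manifest = {
        "seed": config.seed,
        "k_range": [config.k_min, config.k_max],
        "coherence_tolerance": config.coherence_tolerance,
        "eliminated_keywords": sorted(config.eliminated_keywords),
        "stages": {
            "sentiment": config.do_sentiment,
            "topics": config.do_topics,
            "labeled": config.do_labeled,
        },
    }
    tweets, labeled = _load_inputs(config)
    clean_config = CleaningConfig().with_keywords(config.eliminated_keywords)

    stage = "clean"
    try:
        processed, clean_report = preprocess_corpus(tweets, clean_config)
        report.cleaning = clean_report.as_dict()
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineStageError(stage, exc) from exc

    scores = None
    if config.do_sentiment:
        stage = "score"
        try:
            scores = score_corpus(tweets)
            counts = {
                p: sum(1 for s in scores if s.polarity == p)
                for p in ("positive", "negative", "neutral")
            }
            pct = proportions(list(counts.values()), 2)
            hist = intensity_histogram(scores)
            term = term_stratified_counts(tweets, scores, config.term)
            report.sentiment = {
                "n_scored": len(scores),
                "counts": counts,
                "percents": dict(zip(counts, pct)),
                "intensity_histogram": {"counts": hist.counts, "percents": hist.percents},
                "term": {
                    "term": term.term,
                    "positive": term.positive,
                    "negative": term.negative,
                    "neutral": term.neutral,
                    "total_matched": term.total_matched,
                    "percent_of_corpus": term.percent_of_corpus,
                },
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc

    if config.do_topics:
        stage = "topics"
        try:
            nonempty = [p for p in processed if p.tokens]
            bow = build_bow(nonempty)
            scan = scan_topic_counts(
                bow, config.k_min, config.k_max, seed=config.seed
            )
            k = select_optimal_k(scan.curve, scan.models, config.coherence_tolerance)
            model = scan.models[k]
            word_lists = {
                t: [w for w, _ in top_words(model, t, config.topic_top_n)]
                for t in range(model.k)
            }
            pos_words: frozenset[str] = frozenset()
            neg_words: frozenset[str] = frozenset()
            if labeled:
                pos_words = class_top_words(labeled, "positive", config.class_top_n, clean_config)
                neg_words = class_top_words(labeled, "negative", config.class_top_n, clean_config)
            polarity = assign_all_topics(word_lists, opinion_lexicon(), pos_words, neg_words)
            report.topics = {
                "coherence_curve": scan.curve.points,
                "selected_k": k,
                "topic_labels": polarity.labels,
                "topic_counts": {
                    t: [c.positive, c.negative, c.neutral]
                    for t, c in polarity.counts.items()
                },
                "polarity_percents": polarity_proportions(polarity),
                "top_words": word_lists,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc

    if config.do_labeled and labeled:
        stage = "labeled"
        try:
            tables = {
                cls: [
                    list(row)
                    for row in top_frequent_words(
                        labeled, cls, config.labeled_table_n, clean_config
                    ).rows
                ]
                for cls in ("positive", "negative", "neutral")
            }
            report.labeled = {
                "n_labeled": len(labeled),
                "class_counts": {
                    cls: sum(1 for lt in labeled if lt.label == cls)
                    for cls in ("positive", "negative", "neutral")
                },
                "class_percents": class_proportions(labeled),
                "top_word_tables": tables,
            }
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError(stage, exc) from exc

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / "report.json")
        with (out / "manifest.json").open("w", encoding="utf-8") as fh:
            json.dump(report.manifest, fh, indent=2, sort_keys=True)
    return report
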