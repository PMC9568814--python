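"""Data model and readers/writers for tweet corpora, labels, keyword configs, and word vectors.

The on-disk conventions are fixed: JSON Lines records carry ``id``, ``date`` and
``text`` fields; CSV files carry ``tweet_id``, ``created_at`` and ``text`` columns;
labeled subsets are CSV with ``text`` and ``label`` columns; word vectors use the
plain-text format of one word followed by space-separated floats per line, no
header. Text is NFC-normalized on read so downstream token comparisons are stable.
"""

from __future__ import annotations

import csv
import json
import logging
import unicodedata
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)

POLARITIES = ("positive", "negative", "neutral")


@dataclass(frozen=True)
class RawTweet:
    """One microblog post: opaque id, calendar date, and the raw unicode text."""

    tweet_id: str
    created_at: date
    text: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(f"tweet {self.tweet_id!r}: text is empty")


@dataclass(frozen=True)
class LabeledTweet:
    """A tweet with a human polarity annotation (positive/negative/neutral)."""

    tweet: RawTweet
    label: str

    def __post_init__(self) -> None:
        if self.label not in POLARITIES:
            raise ValueError(f"invalid label {self.label!r}; expected one of {POLARITIES}")


@dataclass(frozen=True)
class KeywordConfig:
    """Panel keyword categories: work nouns, sentiment adjectives, explicit phrases.

    Entries are lowercase, deduplicated, non-empty. Multi-word entries are kept as
    phrases; composition and matching decide how to split them.
    """

    category1: frozenset[str]
    category2: frozenset[str]
    category3: frozenset[str] = frozenset()

    @staticmethod
    def _clean(entries: Iterable[str]) -> frozenset[str]:
        return frozenset(e.strip().lower() for e in entries if e and e.strip())

    @classmethod
    def from_lists(
        cls,
        category1: Iterable[str],
        category2: Iterable[str],
        category3: Iterable[str] = (),
    ) -> "KeywordConfig":
        return cls(cls._clean(category1), cls._clean(category2), cls._clean(category3))


class WordVectorTable(Mapping[str, np.ndarray]):
    """Word -> dense vector mapping with a fixed dimension.

    Lookup of an absent word raises ``KeyError`` (``get`` returns ``None``); a miss
    is distinguishable and never silently a zero vector.
    """

    def __init__(self, vectors: Mapping[str, np.ndarray]):
        if not vectors:
            raise ValueError("word vector table is empty")
        dims = {len(v) for v in vectors.values()}
        if len(dims) != 1:
            raise ValueError(f"inconsistent vector dimensions: {sorted(dims)}")
        self._vectors = {w: np.asarray(v, dtype=float) for w, v in vectors.items()}
        self.dim = dims.pop()
        if self.dim <= 0:
            raise ValueError("vector dimension must be positive")

    def __getitem__(self, word: str) -> np.ndarray:
        return self._vectors[word]

    def __iter__(self) -> Iterator[str]:
        return iter(self._vectors)

    def __len__(self) -> int:
        return len(self._vectors)

    @property
    def words(self) -> list[str]:
        return list(self._vectors)


def _nfc(s: str) -> str:
    return unicodedata.normalize("NFC", s)


def _parse_date(value: str) -> date:
    # ISO-8601; a trailing time-of-day is ignored (analyses use only a date window).
    return date.fromisoformat(str(value).strip()[:10])


def _make_tweet(tweet_id: str, created_at: str, text: str) -> RawTweet:
    return RawTweet(str(tweet_id), _parse_date(created_at), _nfc(str(text)))


def read_tweets(path: str | Path, format: str = "jsonl") -> tuple[list[RawTweet], int]:
    """Read a tweet corpus; returns ``(tweets, n_skipped)``.

    Malformed records are counted and skipped with a logged warning; a duplicate
    ``tweet_id`` keeps the first occurrence. Order is preserved.
    """
    path = Path(path)
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")
    tweets: list[RawTweet] = []
    seen: set[str] = set()
    skipped = 0

    def _add(raw_id, raw_date, raw_text, lineno: int) -> None:
        nonlocal skipped
        try:
            tw = _make_tweet(raw_id, raw_date, raw_text)
        except (ValueError, TypeError) as exc:
            logger.warning("%s line %d: skipping malformed record (%s)", path, lineno, exc)
            skipped += 1
            return
        if tw.tweet_id in seen:
            logger.warning("%s line %d: duplicate tweet_id %r, keeping first", path, lineno, tw.tweet_id)
            return
        seen.add(tw.tweet_id)
        tweets.append(tw)

    if format == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                    _add(rec["id"], rec["date"], rec["text"], lineno)
                except (json.JSONDecodeError, KeyError) as exc:
                    logger.warning("%s line %d: skipping malformed record (%s)", path, lineno, exc)
                    skipped += 1
    else:
        with path.open(encoding="utf-8", newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), 2):
                try:
                    _add(row["tweet_id"], row["created_at"], row["text"], lineno)
                except KeyError as exc:
                    logger.warning("%s line %d: skipping malformed record (%s)", path, lineno, exc)
                    skipped += 1
    return tweets, skipped


def write_tweets(tweets: Sequence[RawTweet], path: str | Path, format: str = "jsonl") -> None:
    """Write a tweet corpus; the exact inverse of :func:`read_tweets`."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for tw in tweets:
                fh.write(
                    json.dumps(
                        {"id": tw.tweet_id, "date": tw.created_at.isoformat(), "text": tw.text},
                        ensure_ascii=False,
                    )
                    + "\n"
                )
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["tweet_id", "created_at", "text"])
            for tw in tweets:
                writer.writerow([tw.tweet_id, tw.created_at.isoformat(), tw.text])
    else:
        raise ValueError(f"unknown format {format!r}")


def read_labels(path: str | Path) -> list[LabeledTweet]:
    """Read a human-labeled subset (CSV with ``text`` and ``label`` columns).

    Labels are normalized to the lowercase canonical set; any other label is a
    fatal validation error naming the offending row. Optional ``tweet_id`` and
    ``created_at`` columns are honored; otherwise ids are row numbers and the
    date defaults to 1970-01-01.
    """
    path = Path(path)
    out: list[LabeledTweet] = []
    with path.open(encoding="utf-8", newline="") as fh:
        for rowno, row in enumerate(csv.DictReader(fh), 2):
            label = str(row["label"]).strip().lower()
            if label not in POLARITIES:
                raise ValueError(f"{path} row {rowno}: invalid label {row['label']!r}")
            tweet = _make_tweet(
                row.get("tweet_id") or f"row{rowno}",
                row.get("created_at") or "1970-01-01",
                row["text"],
            )
            out.append(LabeledTweet(tweet, label))
    return out


def write_labels(labeled: Sequence[LabeledTweet], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["tweet_id", "created_at", "text", "label"])
        for lt in labeled:
            writer.writerow(
                [lt.tweet.tweet_id, lt.tweet.created_at.isoformat(), lt.tweet.text, lt.label]
            )


def read_word_vectors(path: str | Path) -> WordVectorTable:
    """Read a plain-text word-vector file (word followed by floats, one per line)."""
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split(" ")
            if len(parts) < 2:
                continue
            word, values = parts[0], parts[1:]
            try:
                vec = np.array([float(v) for v in values])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            if dim is None:
                dim = len(vec)
            elif len(vec) != dim:
                raise ValueError(
                    f"{path} line {lineno}: dimension {len(vec)} != expected {dim}"
                )
            vectors[_nfc(word)] = vec
    return WordVectorTable(vectors)


def write_word_vectors(table: WordVectorTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for word in table:
            fh.write(word + " " + " ".join(f"{v:.6g}" for v in table[word]) + "\n")


def read_keyword_config(path: str | Path) -> KeywordConfig:
    """Read a YAML keyword config with ``category1``/``category2``/``category3`` lists."""
    with Path(path).open(encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return KeywordConfig.from_lists(
        raw.get("category1", ()), raw.get("category2", ()), raw.get("category3", ())
    )


def panel_keyword_config() -> KeywordConfig:
    """The packaged panel-elicited keyword categories."""
    return read_keyword_config(Path(__file__).parent / "data" / "panel_keywords.yaml")
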