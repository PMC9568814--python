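import json
from datetime import date

import numpy as np
import pytest
from hypothesis import given, strategies as st

import worksent as ws

from conftest import tweet

_text_strategy = st.text(
    alphabet=st.characters(blacklist_categories=("Cs", "Cc")), min_size=1, max_size=120
).filter(lambda s: s.strip())


def _write_jsonl(path, records):
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


class TestReadTweets:
    def test_valid_jsonl_preserves_order(self, tmp_path):
        path = tmp_path / "tweets.jsonl"
        _write_jsonl(
            path,
            [
                {"id": "a", "date": "2020-01-01", "text": "first"},
                {"id": "b", "date": "2020-01-02", "text": "second"},
                {"id": "c", "date": "2020-01-03", "text": "third"},
            ],
        )
        tweets, skipped = ws.read_tweets(path)
        assert [t.tweet_id for t in tweets] == ["a", "b", "c"]
        assert [t.text for t in tweets] == ["first", "second", "third"]
        assert tweets[0].created_at == date(2020, 1, 1)
        assert skipped == 0

    def test_malformed_line_counted_and_skipped(self, tmp_path):
        path = tmp_path / "tweets.jsonl"
        path.write_text(
            '{"id": "a", "date": "2020-01-01", "text": "ok"}\n'
            "this is not json\n"
            '{"id": "b", "date": "2020-01-02", "text": "also ok"}\n'
        )
        tweets, skipped = ws.read_tweets(path)
        assert [t.tweet_id for t in tweets] == ["a", "b"]
        assert skipped == 1

    def test_empty_file_gives_empty_sequence(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        tweets, skipped = ws.read_tweets(path)
        assert tweets == [] and skipped == 0

    def test_duplicate_id_keeps_first(self, tmp_path):
        path = tmp_path / "tweets.jsonl"
        _write_jsonl(
            path,
            [
                {"id": "a", "date": "2020-01-01", "text": "kept"},
                {"id": "a", "date": "2020-01-02", "text": "dropped"},
            ],
        )
        tweets, skipped = ws.read_tweets(path)
        assert len(tweets) == 1 and tweets[0].text == "kept"
        # a duplicate is not silently lost: it is not counted as a skip either,
        # but the reader never drops more than it reports plus duplicates
        assert skipped == 0

    def test_missing_file_is_fatal(self, tmp_path):
        with pytest.raises(OSError):
            ws.read_tweets(tmp_path / "nope.jsonl")

    @given(
        texts=st.lists(_text_strategy, min_size=1, max_size=8),
        fmt=st.sampled_from(["jsonl", "csv"]),
    )
    def test_round_trip(self, tmp_path_factory, texts, fmt):
        tweets = [
            ws.RawTweet(f"id{i}", date(2019, 1, 1 + i % 28), t) for i, t in enumerate(texts)
        ]
        path = tmp_path_factory.mktemp("rt") / f"corpus.{fmt}"
        ws.write_tweets(tweets, path, fmt)
        back, skipped = ws.read_tweets(path, fmt)
        assert skipped == 0
        assert [(t.tweet_id, t.created_at) for t in back] == [
            (t.tweet_id, t.created_at) for t in tweets
        ]
        import unicodedata

        assert [t.text for t in back] == [unicodedata.normalize("NFC", t.text) for t in tweets]


class TestReadLabels:
    def test_case_normalization(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text('text,label\n"great day at work",Positive\n')
        labeled = ws.read_labels(path)
        assert labeled[0].label == "positive"

    def test_invalid_label_is_fatal_and_names_row(self, tmp_path):
        path = tmp_path / "labels.csv"
        path.write_text('text,label\n"fine",neutral\n"odd",mixed\n')
        with pytest.raises(ValueError, match="row 3"):
            ws.read_labels(path)

    def test_large_subset_row_count(self, tmp_path):
        path = tmp_path / "labels.csv"
        labels = ["positive", "negative", "neutral"]
        with path.open("w") as fh:
            fh.write("text,label\n")
            for i in range(3200):
                fh.write(f"tweet number {i},{labels[i % 3]}\n")
        assert len(ws.read_labels(path)) == 3200


class TestWordVectors:
    def test_toy_file(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("a 1 0 0\nb 0 1 0\nc 0 0 1\nd 1 1 0\n")
        table = ws.read_word_vectors(path)
        assert len(table) == 4 and table.dim == 3
        assert np.allclose(table["d"], [1, 1, 0])

    def test_absent_word_is_a_miss(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("a 1 0\n")
        table = ws.read_word_vectors(path)
        assert table.get("zzz") is None
        with pytest.raises(KeyError):
            table["zzz"]

    def test_inconsistent_dimension_is_fatal(self, tmp_path):
        path = tmp_path / "vec.txt"
        path.write_text("a 1 0 0\nb 1 0 0 0\n")
        with pytest.raises(ValueError, match="dimension"):
            ws.read_word_vectors(path)


class TestKeywordConfig:
    def test_packaged_panel_config_is_clean(self):
        config = ws.panel_keyword_config()
        for cat in (config.category1, config.category2, config.category3):
            assert cat
            assert all(e == e.lower() and e.strip() == e and e for e in cat)

    def test_yaml_round_trip_normalizes(self, tmp_path):
        path = tmp_path / "kw.yaml"
        path.write_text("category1: [Work, work, ' office ']\ncategory2: [bad]\n")
        config = ws.read_keyword_config(path)
        assert config.category1 == frozenset({"work", "office"})


def test_empty_tweet_text_rejected():
    with pytest.raises(ValueError):
        ws.RawTweet("x", date(2020, 1, 1), "   ")


def test_invalid_polarity_label_rejected():
    with pytest.raises(ValueError):
        ws.LabeledTweet(tweet("fine"), "mixed")
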