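"""Packaged lexical resources: valence lexicon, opinion word sets, stopwords, contractions.

The valence lexicon maps sentiment-bearing words to a signed strength on a
nominal [-4, +4] scale; it doubles as the source of the binary opinion lexicon
(positive = valence > 0, negative = valence < 0), which keeps the two resources
consistent by construction and the sets disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

_DATA = Path(__file__).parent / "data"


@dataclass(frozen=True)
class OpinionLexicon:
    """Disjoint positive and negative opinion word sets."""

    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError("opinion lexicon sets must be non-empty")
        overlap = self.positive & self.negative
        if overlap:
            raise ValueError(f"opinion lexicon sets overlap: {sorted(overlap)[:5]}")


@lru_cache(maxsize=1)
def valence_lexicon() -> dict[str, float]:
    out: dict[str, float] = {}
    with (_DATA / "valence_lexicon.tsv").open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            word, value = line.rstrip("\n").split("\t")
            out[word] = float(value)
    return out


@lru_cache(maxsize=1)
def opinion_lexicon() -> OpinionLexicon:
    lex = valence_lexicon()
    return OpinionLexicon(
        positive=frozenset(w for w, v in lex.items() if v > 0),
        negative=frozenset(w for w, v in lex.items() if v < 0),
    )


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    with (_DATA / "stopwords.txt").open(encoding="utf-8") as fh:
        return frozenset(w.strip() for w in fh if w.strip())


@lru_cache(maxsize=1)
def contraction_map() -> dict[str, str]:
    out: dict[str, str] = {}
    with (_DATA / "contractions.tsv").open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            contraction, expansion = line.rstrip("\n").split("\t")
            out[contraction] = expansion
    return out
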