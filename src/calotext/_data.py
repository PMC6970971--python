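"""Loaders for the small versioned data tables shipped with the package.

Everything cleaning-related (stopwords, emoticon names, contraction splits)
is pinned in-package so that tokenized output never drifts with an external
library release.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources


def _lines(name: str) -> list[str]:
    text = resources.files("calotext.data").joinpath(name).read_text(encoding="utf-8")
    out = []
    for line in text.splitlines():
        line = line.rstrip("\n")
        if not line or line.lstrip().startswith("#"):
            continue
        out.append(line)
    return out


@lru_cache(maxsize=None)
def stopwords() -> frozenset[str]:
    return frozenset(_lines("stopwords.txt"))


@lru_cache(maxsize=None)
def emoticon_map() -> dict[str, str]:
    """Mapping emoticon/emoji symbol -> textual name."""
    mapping: dict[str, str] = {}
    for line in _lines("emoticons.tsv"):
        symbol, _, name = line.partition("\t")
        if symbol and name:
            mapping[symbol] = name
    return mapping


@lru_cache(maxsize=None)
def contraction_table() -> dict[str, tuple[str, ...]]:
    """Mapping informal contraction -> its split, e.g. 'gonna' -> ('gon','na')."""
    table: dict[str, tuple[str, ...]] = {}
    for line in _lines("contractions.tsv"):
        word, _, split = line.partition("\t")
        if word and split:
            table[word] = tuple(split.split())
    return table


@lru_cache(maxsize=None)
def category_keywords() -> dict[str, frozenset[str]]:
    """Fallback keyword lists used to infer a food's category when the
    lexicon table carries no explicit category column."""
    return {
        "vegetable": frozenset(_lines("vegetables.txt")),
        "fruit": frozenset(_lines("fruits.txt")),
        "juice": frozenset(_lines("juices.txt")),
    }


def gold_inventory_lines() -> list[tuple[str, str]]:
    """Raw (phrase, tag) pairs of the packaged gold-standard MWE inventory."""
    pairs = []
    for line in _lines("idioms.txt"):
        phrase, _, tag = line.partition("\t")
        pairs.append((phrase.strip(), tag.strip() or "idiom"))
    return pairs
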