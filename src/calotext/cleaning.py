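"""Five-step normalization of short social-media posts.

The pipeline reduces a raw post to lowercase alphabetic content tokens:

1. emoticons and emoji are replaced by their textual names,
2. all text is lowercased,
3. the text is tokenized (informal contractions split by a rule table)
   and stopwords are removed,
4. special characters are stripped, keeping hashtagged text
   (``#rofl`` -> ``rofl``); URLs and @mentions are deleted outright,
5. numbers are removed.

Sentence-like boundaries (``. ! ?``) observed in the raw text are recorded
on the cleaned post so that downstream phrase detection never matches a
multiword expression across a sentence break.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from ._data import contraction_table, emoticon_map, stopwords

__all__ = [
    "RawPost",
    "CleanPost",
    "convert_emoticons",
    "to_lowercase",
    "tokenize",
    "remove_stopwords",
    "strip_special_characters",
    "remove_numbers",
    "clean",
    "clean_steps",
    "clean_text",
    "singularize",
    "canonicalize",
    "TweetCleaner",
]

_NON_ALNUM_RE = re.compile(r"[^0-9a-zA-Z]+")
_DIGIT_RE = re.compile(r"[0-9]+")
_SENTENCE_SPLIT_RE = re.compile(r"[.!?]+(?:\s|$)")


@dataclass(frozen=True)
class RawPost:
    """A post as collected: opaque id, text, region code, optional timestamp."""

    id: str
    text: str
    region: str = "all"
    timestamp: str | None = None


@dataclass(frozen=True)
class CleanPost:
    """A post reduced to ordered content tokens.

    ``boundaries`` holds cumulative token counts at sentence ends, e.g.
    tokens ``[a, b, c, d]`` with boundaries ``[2, 4]`` means two sentences
    ``[a, b]`` and ``[c, d]``.
    """

    id: str
    region: str
    tokens: tuple[str, ...]
    boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.boundaries and self.boundaries[-1] != len(self.tokens):
            raise ValueError("boundaries must end at len(tokens)")


# ---------------------------------------------------------------------------
# individual steps


def convert_emoticons(text: str) -> str:
    """Replace every emoticon/emoji with its space-separated textual name.

    ASCII emoticons are recognized as whole whitespace-delimited tokens
    (``:-)`` -> ``Happy face smiley``); emoji codepoints are replaced
    wherever they occur.  Unmapped symbols are left untouched for the later
    special-character step.
    """
    mapping = emoticon_map()
    # emoji (non-ASCII keys) can be glued to words; substitute globally
    for symbol, name in mapping.items():
        if not symbol.isascii() and symbol in text:
            text = text.replace(symbol, f" {name} ")
    parts = [mapping.get(tok, tok) for tok in text.split()]
    return " ".join(parts)


def to_lowercase(text: str) -> str:
    """Unicode-aware lowercasing; idempotent."""
    return text.lower()


def tokenize(text: str) -> list[str]:
    """Whitespace tokenization with rule-table contraction splitting.

    ``gonna`` becomes ``gon na``; punctuation (including ``#``) stays
    attached at this stage — it is handled by the special-character step.
    """
    table = contraction_table()
    out: list[str] = []
    for tok in text.split():
        split = table.get(tok.lower())
        if split is not None:
            out.extend(split)
        else:
            out.append(tok)
    return out


def remove_stopwords(tokens: Sequence[str]) -> list[str]:
    """Drop tokens in the packaged stopword list, preserving order.

    Membership is checked on the lowercased token with surrounding
    punctuation ignored, so ``The,`` is still recognized as a stopword.
    """
    stop = stopwords()
    kept = []
    for tok in tokens:
        bare = _NON_ALNUM_RE.sub("", tok.lower())
        if tok.lower() in stop or bare in stop:
            continue
        kept.append(tok)
    return kept


def strip_special_characters(tokens: Sequence[str]) -> list[str]:
    """Delete non-alphanumeric characters from each token.

    Hashtagged text is kept (``#rofl`` -> ``rofl``); URLs and @mentions are
    deleted outright since their residues are non-lexical noise.  Tokens
    emptied by stripping are dropped.
    """
    out = []
    for tok in tokens:
        low = tok.lower()
        if low.startswith(("http://", "https://", "www.")) or low.startswith("@"):
            continue
        stripped = _NON_ALNUM_RE.sub("", tok)
        if stripped:
            out.append(stripped)
    return out


def remove_numbers(tokens: Sequence[str]) -> list[str]:
    """Delete digits inside tokens; purely numeric tokens disappear."""
    out = []
    for tok in tokens:
        stripped = _DIGIT_RE.sub("", tok)
        if stripped:
            out.append(stripped)
    return out


# ---------------------------------------------------------------------------
# composition


def _step1(text: str) -> str:
    """Emoticon conversion as it appears in the pipeline's first stage.

    Plain words are case-folded already here, while hashtag tokens and the
    inserted emoticon names keep their capitalization until the dedicated
    lowercase stage.
    """
    mapping = emoticon_map()
    for symbol, name in mapping.items():
        if not symbol.isascii() and symbol in text:
            text = text.replace(symbol, f" {name} ")
    parts = []
    for tok in text.split():
        if tok in mapping:
            parts.append(mapping[tok])
        elif tok.startswith("#"):
            parts.append(tok)
        else:
            parts.append(tok.lower())
    return " ".join(parts)


def clean_steps(text: str) -> list[str]:
    """Return the five intermediate texts of the cleaning pipeline.

    Index 0 is the output after emoticon conversion, index 4 the final
    text whose whitespace split is the post's token sequence.
    """
    text = unicodedata.normalize("NFKC", text)
    s1 = _step1(text)
    s2 = to_lowercase(s1)
    toks3 = remove_stopwords(tokenize(s2))
    toks4 = strip_special_characters(toks3)
    toks5 = remove_numbers(toks4)
    return [s1, s2, " ".join(toks3), " ".join(toks4), " ".join(toks5)]


def clean_text(text: str) -> tuple[tuple[str, ...], tuple[int, ...]]:
    """Clean raw text to content tokens plus sentence boundaries.

    A token reduced *to* a stopword by character/digit stripping (e.g.
    ``0I`` -> ``i``) is dropped as well, so stopword removal stays a fixed
    point of the whole pipeline.
    """
    text = unicodedata.normalize("NFKC", text)
    stop = stopwords()
    tokens: list[str] = []
    boundaries: list[int] = []
    for sentence in _SENTENCE_SPLIT_RE.split(text):
        if not sentence.strip():
            continue
        tokens.extend(t for t in clean_steps(sentence)[4].split() if t not in stop)
        if not boundaries or len(tokens) > boundaries[-1]:
            boundaries.append(len(tokens))
    return tuple(tokens), tuple(boundaries)


def clean(raw: RawPost) -> CleanPost:
    """Apply the full pipeline to one post."""
    tokens, boundaries = clean_text(raw.text)
    return CleanPost(id=raw.id, region=raw.region, tokens=tokens, boundaries=boundaries)


# ---------------------------------------------------------------------------
# canonicalization shared with the lexicon / phrase inventory


def singularize(token: str) -> str:
    """Heuristic plural stripping applied at phrase-match time only.

    ``potatoes`` -> ``potato``, ``fries`` -> ``fry``, ``eyes`` -> ``eye``;
    short tokens and -ss/-us/-is endings are left alone.
    """
    if len(token) <= 3 or not token.endswith("s"):
        return token
    if token.endswith(("ss", "us", "is")):
        return token
    if token.endswith(("oes", "xes", "zes", "ches", "shes", "sses")):
        return token[:-2]
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    return token[:-1]


def canonicalize(phrase: str, singular: bool = True) -> tuple[str, ...]:
    """Canonical content tokens of a lexicon or inventory phrase.

    Applies the cleaning pipeline minus the emoticon step (lowercase,
    tokenize, stopword removal, special characters, numbers), then optional
    plural stripping.  Cleaning is a fixed point of this map, so lexicon
    keys and cleaned post tokens live in the same space.
    """
    text = unicodedata.normalize("NFKC", phrase)
    toks = remove_numbers(strip_special_characters(remove_stopwords(tokenize(to_lowercase(text)))))
    if singular:
        toks = [singularize(t) for t in toks]
    return tuple(toks)


class TweetCleaner(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer over raw posts.

    ``transform`` accepts an iterable of strings or :class:`RawPost` and
    returns a list of :class:`CleanPost` (strings get synthetic ids).
    """

    def fit(self, X: Iterable[object], y: object = None) -> "TweetCleaner":
        self.n_features_in_ = 1
        return self

    def transform(self, X: Iterable[object]) -> list[CleanPost]:
        out = []
        for i, item in enumerate(X):
            if isinstance(item, RawPost):
                out.append(clean(item))
            else:
                tokens, boundaries = clean_text(str(item))
                out.append(CleanPost(id=str(i), region="all", tokens=tokens, boundaries=boundaries))
        return out
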