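"""Multiword-expression detection over cleaned content tokens.

A multiword expression (MWE) is a token sequence with unitary meaning —
``sweet potato`` is a food, ``apple of my eye`` is an idiom in which
``apple`` is not a food.  Function words joining an MWE's content words
("of", "my", ...) act as linkers; because the cleaning pipeline already
removes them as stopwords, inventory forms are stored stopword-free
(``apple of my eye`` -> ``apple eye``) and matching runs over adjacent
content tokens only.

Matching is greedy leftmost-longest with candidate length capped at
:data:`MAX_FORM_LEN` content tokens; plurals are folded at match time only
(``potatoes`` matches ``potato``) while surface forms are preserved in the
output.  Tokens inside matched *idiom* forms are masked so that idiomatic
uses of food words stay invisible to caloric counting and to
weak-supervision labeling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from sklearn.base import BaseEstimator, TransformerMixin

from ._data import gold_inventory_lines
from .cleaning import CleanPost, canonicalize, singularize

__all__ = [
    "MAX_FORM_LEN",
    "PhraseMatch",
    "PhraseGroup",
    "PhraseInventory",
    "extract_content_groups",
    "match_mwe",
    "flag_food_idioms",
    "mask_post",
    "PhraseMatcher",
]

logger = logging.getLogger(__name__)

MAX_FORM_LEN = 4


@dataclass(frozen=True)
class PhraseMatch:
    form: tuple[str, ...]          # canonical inventory form
    positions: tuple[int, ...]     # strictly increasing surface positions
    tag: str = "compound"          # idiom | compound | lexicon


@dataclass(frozen=True)
class PhraseGroup:
    """Content tokens of one sentence-like span with their MWE matches."""

    surface_tokens: tuple[str, ...]
    matches: tuple[PhraseMatch, ...] = ()
    offset: int = 0                # start index within the owning post

    @property
    def matched_positions(self) -> frozenset[int]:
        return frozenset(p for m in self.matches for p in m.positions)

    @property
    def residual_tokens(self) -> tuple[str, ...]:
        hit = self.matched_positions
        return tuple(t for i, t in enumerate(self.surface_tokens) if i not in hit)

    @property
    def token_set(self) -> frozenset[str]:
        return frozenset(self.surface_tokens)


class PhraseInventory:
    """Set of canonical multiword forms with a tag and source per entry."""

    def __init__(self, entries: Mapping[tuple[str, ...], str] | None = None, source: str = "gold"):
        self.forms: dict[tuple[str, ...], str] = {}
        self.sources: dict[tuple[str, ...], str] = {}
        if entries:
            for form, tag in entries.items():
                self.add(form, tag=tag, source=source)

    def __len__(self) -> int:
        return len(self.forms)

    def __contains__(self, form: tuple[str, ...]) -> bool:
        return tuple(form) in self.forms

    def add(self, phrase: str | Sequence[str], tag: str = "compound", source: str = "gold") -> None:
        form = canonicalize(phrase) if isinstance(phrase, str) else tuple(singularize(t) for t in phrase)
        if len(form) > MAX_FORM_LEN:
            warnings.warn(f"inventory form {form} longer than {MAX_FORM_LEN} tokens; truncated")
            form = form[:MAX_FORM_LEN]
        if len(form) < 2:
            logger.warning("skipping inventory entry %r: fewer than 2 content tokens", phrase)
            return
        self.forms[form] = tag
        self.sources[form] = source

    def subset(self, tag: str) -> "PhraseInventory":
        inv = PhraseInventory()
        for form, t in self.forms.items():
            if t == tag:
                inv.forms[form] = t
                inv.sources[form] = self.sources[form]
        return inv

    @classmethod
    def from_file(cls, path: str | Path, source: str | None = None) -> "PhraseInventory":
        """Read one phrase per line, optional tab-separated tag (idiom|compound)."""
        inv = cls()
        src = source or str(path)
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            phrase, _, tag = line.partition("\t")
            inv.add(phrase.strip(), tag=(tag.strip() or "compound"), source=src)
        return inv

    @classmethod
    def gold(cls) -> "PhraseInventory":
        """The packaged gold-standard idiom/compound inventory."""
        inv = cls()
        for phrase, tag in gold_inventory_lines():
            inv.add(phrase, tag=tag, source="gold")
        return inv

    @classmethod
    def from_lexicon_keys(cls, keys: Iterable[str], tag: str = "lexicon") -> "PhraseInventory":
        inv = cls()
        for key in keys:
            form = tuple(key.split())
            if len(form) >= 2:
                inv.add(form, tag=tag, source="lexicon")
        return inv


def extract_content_groups(
    tokens: Sequence[str], boundaries: Sequence[int] | None = None
) -> list[PhraseGroup]:
    """Partition content tokens into sentence-spans (matches left empty)."""
    tokens = tuple(tokens)
    if not tokens:
        return []
    if not boundaries:
        boundaries = (len(tokens),)
    groups = []
    start = 0
    for end in boundaries:
        if end > start:
            groups.append(PhraseGroup(surface_tokens=tokens[start:end], offset=start))
        start = end
    if start < len(tokens):  # trailing tokens not covered by a boundary
        groups.append(PhraseGroup(surface_tokens=tokens[start:], offset=start))
    return groups


def match_mwe(group: PhraseGroup, inventory: PhraseInventory) -> PhraseGroup:
    """Greedy leftmost-longest matching of adjacent content tokens.

    At each position the longest canonical window (up to
    :data:`MAX_FORM_LEN`) present in the inventory wins; matched spans are
    disjoint by construction.
    """
    surface = group.surface_tokens
    canon = [singularize(t) for t in surface]
    n = len(surface)
    matches: list[PhraseMatch] = []
    i = 0
    while i < n:
        hit = None
        for length in range(min(MAX_FORM_LEN, n - i), 1, -1):
            form = tuple(canon[i : i + length])
            if form in inventory:
                hit = PhraseMatch(
                    form=form,
                    positions=tuple(range(i, i + length)),
                    tag=inventory.forms[form],
                )
                break
        if hit is not None:
            matches.append(hit)
            i = hit.positions[-1] + 1
        else:
            i += 1
    return replace(group, matches=tuple(matches))


def flag_food_idioms(
    groups: Sequence[PhraseGroup],
    n_tokens: int,
    idiom_inventory: PhraseInventory,
) -> tuple[list[PhraseGroup], list[bool]]:
    """Mask every token lying inside a matched idiom form.

    Returns the groups with idiom matches filled plus a per-token boolean
    mask over the post's ``n_tokens`` positions (True = excluded from
    caloric counting and weak labeling).  Idioms take precedence over any
    food-lexicon form sharing tokens: masking happens first, and downstream
    matching only ever sees unmasked positions.
    """
    idioms = idiom_inventory.subset("idiom") if any(
        t != "idiom" for t in idiom_inventory.forms.values()
    ) else idiom_inventory
    mask = [False] * n_tokens
    matched_groups = []
    for group in groups:
        g = match_mwe(group, idioms)
        for m in g.matches:
            for p in m.positions:
                mask[group.offset + p] = True
        matched_groups.append(g)
    return matched_groups, mask


def mask_post(post: CleanPost, idiom_inventory: PhraseInventory) -> tuple[list[PhraseGroup], list[bool]]:
    """Convenience: groups + idiom mask for one cleaned post."""
    groups = extract_content_groups(post.tokens, post.boundaries)
    return flag_food_idioms(groups, len(post.tokens), idiom_inventory)


class PhraseMatcher(BaseEstimator, TransformerMixin):
    """sklearn-style transformer filling MWE matches on cleaned posts.

    ``transform`` maps a list of :class:`CleanPost` to a list of
    ``(groups, mask)`` pairs using the configured inventory (the packaged
    gold inventory by default).
    """

    def __init__(self, inventory: PhraseInventory | None = None):
        self.inventory = inventory

    def fit(self, X: Iterable[CleanPost], y: object = None) -> "PhraseMatcher":
        self.inventory_ = self.inventory if self.inventory is not None else PhraseInventory.gold()
        return self

    def transform(self, X: Iterable[CleanPost]) -> list[tuple[list[PhraseGroup], list[bool]]]:
        if not hasattr(self, "inventory_"):
            self.fit([])
        out = []
        for post in X:
            groups, mask = mask_post(post, self.inventory_)
            matched = [match_mwe(g, self.inventory_) for g in groups]
            out.append((matched, mask))
        return out
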