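"""Caloric intake, burn and ratio from lexicon mentions.

For a scope (a region, or a whole corpus) let ``f(w)`` be the mention
count of food phrase ``w`` and ``cal(w)`` its per-100 g energy value in
kcal.  The caloric intake indicator is the mention-weighted mean

    C_in = sum_w cal(w) * f(w) / sum_w f(w)

and symmetrically C_out over activity phrases, where an activity's kcal
value is referenced to an assumed average body weight (80.7 kg by default)
and scaled linearly when a subject weight is supplied.  The caloric ratio

    C_rat = C_in / C_out

is a dimensionless intensity: a scope with C_rat > 1 mentions consumption
more calorically than expenditure.  Ratios with no activity mentions are
*undefined* and signalled, never coerced to 0 or infinity.

Tokens masked as idiomatic (``piece of cake``) are invisible here: they
never enter a frequency table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .cleaning import CleanPost, singularize
from .errors import SchemaError, UndefinedCaloricResult
from .lexicon import Lexicon
from .phrases import MAX_FORM_LEN, PhraseInventory, mask_post

__all__ = [
    "EngineConfig",
    "FrequencyTable",
    "CaloricSummary",
    "count_mentions",
    "caloric_intake",
    "caloric_burn",
    "caloric_ratio",
    "regional_summary",
    "top_k",
    "population_share_above",
    "summary_frame",
    "read_populations",
]

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE_WEIGHT = 80.7  # kg, assumed average adult body weight


@dataclass(frozen=True)
class EngineConfig:
    """Tunables of the caloric engine.

    reference_weight: body weight (kg) at which activity kcal values are
        tabulated; subject_weight: optional weight to rescale burns to;
        min_mentions_per_region: below this total a region is flagged
        insufficient instead of summarized.
    """

    reference_weight: float = DEFAULT_REFERENCE_WEIGHT
    subject_weight: float | None = None
    min_mentions_per_region: int = 1

    def __post_init__(self) -> None:
        if self.reference_weight <= 0:
            raise ValueError("reference_weight must be > 0")
        if self.subject_weight is not None and self.subject_weight <= 0:
            raise ValueError("subject_weight must be > 0")

    @property
    def weight_scale(self) -> float:
        if self.subject_weight is None:
            return 1.0
        return self.subject_weight / self.reference_weight


@dataclass
class FrequencyTable:
    """Mention counts of canonical lexicon phrases within a scope."""

    counts: dict[str, int] = field(default_factory=dict)
    scope: str = "all"

    def add(self, phrase: str, n: int = 1) -> None:
        self.counts[phrase] = self.counts.get(phrase, 0) + n

    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class CaloricSummary:
    """C_in / C_out / C_rat and mention counts for one scope."""

    scope: str
    c_in: float | None
    c_out: float | None
    c_rat: float | None
    n_food_mentions: int
    n_activity_mentions: int
    reference_weight: float = DEFAULT_REFERENCE_WEIGHT
    flag: str = "ok"  # ok | insufficient | undefined-ratio


# ---------------------------------------------------------------------------
# mention counting


def count_mentions(
    posts: Iterable[CleanPost],
    lexicon: Lexicon,
    idiom_inventory: PhraseInventory | None = None,
    scope: str = "all",
) -> FrequencyTable:
    """Count lexicon-phrase mentions over cleaned posts.

    Within each sentence span, tokens inside matched idioms are masked
    first; the remaining tokens are scanned greedily leftmost-longest
    against lexicon keys (1 to 4 content tokens), never bridging a masked
    position or a sentence boundary.
    """
    keyset = {tuple(k.split()): k for k in lexicon.keys()}
    max_len = min(MAX_FORM_LEN, max((len(k) for k in keyset), default=1))
    table = FrequencyTable(scope=scope)
    for post in posts:
        if idiom_inventory is not None and len(idiom_inventory):
            groups, mask = mask_post(post, idiom_inventory)
        else:
            from .phrases import extract_content_groups

            groups = extract_content_groups(post.tokens, post.boundaries)
            mask = [False] * len(post.tokens)
        for group in groups:
            canon = [singularize(t) for t in group.surface_tokens]
            n = len(canon)
            i = 0
            while i < n:
                if mask[group.offset + i]:
                    i += 1
                    continue
                hit_key = None
                hit_len = 0
                for length in range(min(max_len, n - i), 0, -1):
                    if any(mask[group.offset + j] for j in range(i, i + length)):
                        continue
                    key = keyset.get(tuple(canon[i : i + length]))
                    if key is not None:
                        hit_key, hit_len = key, length
                        break
                if hit_key is not None:
                    table.add(hit_key)
                    i += hit_len
                else:
                    i += 1
    return table


def _weighted_mean(table: FrequencyTable, value_of, what: str) -> float:
    total = table.total()
    if total == 0:
        raise UndefinedCaloricResult(f"no {what} mentions in scope '{table.scope}'")
    num = sum(value_of(k) * f for k, f in sorted(table.counts.items()))
    return num / total


def caloric_intake(
    posts: Iterable[CleanPost],
    food_lexicon: Lexicon,
    idiom_inventory: PhraseInventory | None = None,
    scope: str = "all",
) -> tuple[float, FrequencyTable]:
    """Mention-weighted mean caloric value of food phrases (kcal).

    Raises :class:`UndefinedCaloricResult` when the scope has zero unmasked
    food mentions.
    """
    if len(food_lexicon) == 0:
        raise ValueError("food lexicon is empty")
    table = count_mentions(posts, food_lexicon, idiom_inventory, scope=scope)
    c_in = _weighted_mean(table, food_lexicon.caloric_value, "food")
    return c_in, table


def caloric_burn(
    posts: Iterable[CleanPost],
    activity_lexicon: Lexicon,
    config: EngineConfig | None = None,
    idiom_inventory: PhraseInventory | None = None,
    scope: str = "all",
) -> tuple[float, FrequencyTable]:
    """Mention-weighted mean caloric burn of activity phrases (kcal).

    Activity values are tabulated at ``config.reference_weight``; with a
    ``subject_weight`` they scale by subject_weight / reference_weight.
    """
    if len(activity_lexicon) == 0:
        raise ValueError("activity lexicon is empty")
    config = config or EngineConfig()
    table = count_mentions(posts, activity_lexicon, idiom_inventory, scope=scope)
    scale = config.weight_scale
    c_out = _weighted_mean(table, lambda k: activity_lexicon.caloric_value(k) * scale, "activity")
    return c_out, table


def caloric_ratio(c_in: float | None, c_out: float | None) -> float:
    """C_rat = C_in / C_out; undefined inputs or zero burn are signalled."""
    if c_in is None or c_out is None:
        raise UndefinedCaloricResult("caloric ratio of an undefined input")
    if c_out == 0:
        raise UndefinedCaloricResult("caloric ratio undefined at C_out = 0")
    return c_in / c_out


# ---------------------------------------------------------------------------
# aggregation


def regional_summary(
    posts: Iterable[CleanPost],
    food_lexicon: Lexicon,
    activity_lexicon: Lexicon,
    config: EngineConfig | None = None,
    idiom_inventory: PhraseInventory | None = None,
) -> dict[str, CaloricSummary]:
    """Independent caloric summaries per region.

    Regions whose total mention count falls below
    ``config.min_mentions_per_region`` are flagged ``insufficient``;
    regions lacking food or activity mentions get an undefined (None)
    ratio with flag ``undefined-ratio``.
    """
    config = config or EngineConfig()
    by_region: dict[str, list[CleanPost]] = {}
    for post in posts:
        by_region.setdefault(post.region, []).append(post)

    summaries: dict[str, CaloricSummary] = {}
    for region in sorted(by_region):
        chunk = by_region[region]
        try:
            c_in, food_table = caloric_intake(chunk, food_lexicon, idiom_inventory, scope=region)
        except UndefinedCaloricResult:
            c_in, food_table = None, FrequencyTable(scope=region)
        try:
            c_out, act_table = caloric_burn(chunk, activity_lexicon, config, idiom_inventory, scope=region)
        except UndefinedCaloricResult:
            c_out, act_table = None, FrequencyTable(scope=region)
        n_food, n_act = food_table.total(), act_table.total()
        if n_food + n_act < config.min_mentions_per_region:
            flag, c_rat = "insufficient", None
        else:
            try:
                c_rat, flag = caloric_ratio(c_in, c_out), "ok"
            except UndefinedCaloricResult:
                c_rat, flag = None, "undefined-ratio"
        summaries[region] = CaloricSummary(
            scope=region,
            c_in=c_in,
            c_out=c_out,
            c_rat=c_rat,
            n_food_mentions=n_food,
            n_activity_mentions=n_act,
            reference_weight=config.reference_weight,
            flag=flag,
        )
    return summaries


def top_k(table: FrequencyTable, k: int) -> list[tuple[str, int]]:
    """Top-k phrases by mention count, ties broken lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]


def population_share_above(
    summaries: Mapping[str, CaloricSummary],
    populations: Mapping[str, float],
    threshold: float = 1.0,
) -> float:
    """Percent of the summarized population living in regions whose caloric
    ratio is at or above ``threshold``.

    Regions with an undefined ratio are excluded from both numerator and
    denominator; a summarized region without a population entry is an error.
    """
    total = 0.0
    above = 0.0
    for region, summary in summaries.items():
        if summary.c_rat is None:
            continue
        if region not in populations:
            raise SchemaError(f"no population entry for summarized region '{region}'")
        pop = float(populations[region])
        total += pop
        if summary.c_rat >= threshold:
            above += pop
    if total == 0:
        raise UndefinedCaloricResult("no region with a defined caloric ratio")
    return 100.0 * above / total


def summary_frame(summaries: Mapping[str, CaloricSummary]) -> pd.DataFrame:
    """Tidy frame with header region,c_in,c_out,c_rat,n_food_mentions,
    n_activity_mentions,flag (undefined values empty)."""
    rows = [
        {
            "region": s.scope,
            "c_in": s.c_in,
            "c_out": s.c_out,
            "c_rat": s.c_rat,
            "n_food_mentions": s.n_food_mentions,
            "n_activity_mentions": s.n_activity_mentions,
            "flag": s.flag,
        }
        for s in summaries.values()
    ]
    return pd.DataFrame(rows, columns=["region", "c_in", "c_out", "c_rat", "n_food_mentions", "n_activity_mentions", "flag"])


def read_populations(path: str | Path) -> dict[str, float]:
    """Read a region,population CSV into a mapping."""
    df = pd.read_csv(path)
    for col in ("region", "population"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")
    return dict(zip(df["region"].astype(str), df["population"].astype(float)))
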