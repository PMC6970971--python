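"""Food and activity lexicons with per-100 g nutrient values.

A food lexicon row carries the nutrients of 100 g of the food (fat,
energy in kcal, carbohydrate); an activity lexicon row carries the kcal
burned per mention at a reference body weight.  Lexicon keys are
canonicalized with the same normalization applied to posts (lowercase,
stopword-free, special characters and digits stripped, plurals folded), so
a cleaned post token sequence can be matched against keys directly.

The vegan rule is two-clause: a food is vegan iff the token ``vegan``
appears in its name, or its category is one of vegetable / fruit / juice.
When the table has no category column, the category is inferred from
packaged keyword lists — an approximation, documented as such.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._data import category_keywords
from .cleaning import canonicalize
from .errors import DegenerateInputError, SchemaError

__all__ = [
    "FoodEntry",
    "ActivityEntry",
    "Lexicon",
    "canonical_key",
    "load_food_lexicon",
    "load_activity_lexicon",
    "classify_vegan",
    "infer_category",
    "nutrient_profile",
]

logger = logging.getLogger(__name__)

NUTRIENT_FIELDS = ("fat_100g", "energy_100g", "carbohydrate_100g")
VEGAN_CATEGORIES = frozenset({"vegetable", "fruit", "juice"})
FOOD_COLUMNS = ("food_name", "food_ingredients", "fat_100g", "energy_100g", "carbohydrate_100g")
ACTIVITY_COLUMNS = ("activity_name", "caloric_value")


@dataclass(frozen=True)
class FoodEntry:
    """One food lexicon row; nutrients are per 100 g, energy in kcal."""

    food_name: str
    food_ingredients: tuple[str, ...]
    fat_100g: float
    energy_100g: float
    carbohydrate_100g: float
    category: str = "other"
    is_vegan: bool = False

    @property
    def caloric_value(self) -> float:
        """kcal counted per mention: the per-100 g energy proxy."""
        return self.energy_100g


@dataclass(frozen=True)
class ActivityEntry:
    """One activity row: kcal burned per mention at the reference weight."""

    activity_name: str
    caloric_value: float


@dataclass
class Lexicon:
    """Mapping canonical phrase key -> entry, plus load diagnostics."""

    entries: dict[str, FoodEntry | ActivityEntry]
    kind: str  # "food" | "activity"
    n_rejected: int = 0
    n_merged: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def __getitem__(self, key: str) -> FoodEntry | ActivityEntry:
        return self.entries[key]

    def keys(self):
        return self.entries.keys()

    def caloric_value(self, key: str) -> float:
        return self.entries[key].caloric_value


def canonical_key(name: str) -> str:
    """Canonical lexicon key of a phrase (space-joined canonical tokens)."""
    return " ".join(canonicalize(name))


def infer_category(name_tokens: Iterable[str]) -> str:
    """Fallback category from packaged keyword lists (approximation)."""
    keywords = category_keywords()
    tokens = list(name_tokens)
    for cat in ("juice", "vegetable", "fruit"):
        if any(t in keywords[cat] for t in tokens):
            return cat
    return "other"


def classify_vegan(entry: FoodEntry) -> bool:
    """Two-clause vegan rule.

    True iff the token ``vegan`` appears in the food name, or the entry's
    category is vegetable, fruit or juice; any other food is non-vegan.
    """
    if "vegan" in canonicalize(entry.food_name, singular=False):
        return True
    return entry.category in VEGAN_CATEGORIES


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: object) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column '{col}'")


def load_food_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a food lexicon CSV.

    Rows with non-numeric or negative nutrients, or names that canonicalize
    to nothing, are rejected with a logged reason.  Duplicate canonical
    names are merged by the arithmetic mean of each nutrient (warned);
    ``is_vegan`` is always derived, never read from the file.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, FOOD_COLUMNS, path)
    has_category = "category" in df.columns

    buckets: dict[str, list[dict]] = {}
    n_rejected = 0
    for i, row in df.iterrows():
        name = str(row["food_name"]).strip()
        key = canonical_key(name)
        if not key:
            logger.warning("row %d rejected: empty canonical name %r", i, name)
            n_rejected += 1
            continue
        try:
            nutrients = {f: float(row[f]) for f in NUTRIENT_FIELDS}
        except (TypeError, ValueError):
            logger.warning("row %d (%s) rejected: non-numeric nutrient", i, name)
            n_rejected += 1
            continue
        if any(not math.isfinite(v) or v < 0 for v in nutrients.values()):
            logger.warning("row %d (%s) rejected: negative or non-finite nutrient", i, name)
            n_rejected += 1
            continue
        ingredients = tuple(
            t for part in str(row["food_ingredients"]).split(";")
            for t in canonicalize(part, singular=False)
        )
        category = str(row["category"]).strip().lower() if has_category and str(row.get("category", "")).strip() else ""
        buckets.setdefault(key, []).append(
            {"name": name, "ingredients": ingredients, "category": category, **nutrients}
        )

    entries: dict[str, FoodEntry] = {}
    n_merged = 0
    for key, rows in buckets.items():
        if len(rows) > 1:
            warnings.warn(f"duplicate food name '{key}': merging {len(rows)} rows by nutrient mean")
            n_merged += len(rows) - 1
        nutrients = {f: float(np.mean([r[f] for r in rows])) for f in NUTRIENT_FIELDS}
        ingredients = tuple(dict.fromkeys(t for r in rows for t in r["ingredients"]))
        category = next((r["category"] for r in rows if r["category"]), "")
        if not category:
            category = infer_category(key.split())
        entry = FoodEntry(
            food_name=key,
            food_ingredients=ingredients,
            category=category,
            **nutrients,
        )
        entries[key] = replace(entry, is_vegan=classify_vegan(entry))

    if not entries:
        warnings.warn(f"food lexicon {path} is empty")
    return Lexicon(entries=entries, kind="food", n_rejected=n_rejected, n_merged=n_merged)


def load_activity_lexicon(path: str | Path) -> Lexicon:
    """Load and validate an activity lexicon CSV (activity_name, caloric_value)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, ACTIVITY_COLUMNS, path)

    buckets: dict[str, list[float]] = {}
    n_rejected = 0
    for i, row in df.iterrows():
        name = str(row["activity_name"]).strip()
        key = canonical_key(name)
        if not key:
            logger.warning("row %d rejected: empty canonical activity name %r", i, name)
            n_rejected += 1
            continue
        try:
            value = float(row["caloric_value"])
        except (TypeError, ValueError):
            logger.warning("row %d (%s) rejected: non-numeric caloric_value", i, name)
            n_rejected += 1
            continue
        if not math.isfinite(value) or value < 0:
            logger.warning("row %d (%s) rejected: negative or non-finite caloric_value", i, name)
            n_rejected += 1
            continue
        buckets.setdefault(key, []).append(value)

    entries: dict[str, ActivityEntry] = {}
    n_merged = 0
    for key, values in buckets.items():
        if len(values) > 1:
            warnings.warn(f"duplicate activity '{key}': merging {len(values)} rows by mean")
            n_merged += len(values) - 1
        entries[key] = ActivityEntry(activity_name=key, caloric_value=float(np.mean(values)))

    if not entries:
        warnings.warn(f"activity lexicon {path} is empty")
    return Lexicon(entries=entries, kind="activity", n_rejected=n_rejected, n_merged=n_merged)


# ---------------------------------------------------------------------------
# nutrient density profiles


def _kde_curve(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized Gaussian KDE (Scott's rule) on a 512-point grid spanning
    [min - 3h, max + 3h]; the curve is renormalized on the grid so its
    trapezoidal integral is 1."""
    values = np.asarray(values, dtype=float)
    if np.ptp(values) == 0.0:
        # one distinct value: point-mass limit via a tiny fallback bandwidth
        h = max(abs(values[0]), 1.0) * 1e-3
        center = values[0]
        grid = np.linspace(center - 3 * h, center + 3 * h, 512)
        density = np.exp(-0.5 * ((grid - center) / h) ** 2) / (h * np.sqrt(2 * np.pi))
    else:
        kde = gaussian_kde(values)  # Scott's rule bandwidth
        h = float(np.sqrt(kde.covariance[0, 0]))
        grid = np.linspace(values.min() - 3 * h, values.max() + 3 * h, 512)
        density = kde(grid)
    density = density / np.trapezoid(density, grid)
    return grid, density


def nutrient_profile(lexicon: Lexicon, nutrient: str, split_vegan: bool = False) -> pd.DataFrame:
    """Kernel density estimate of a nutrient across the food lexicon.

    Returns a tidy frame (group, grid_value, density) with group ``all`` or,
    when ``split_vegan``, ``vegan`` / ``non-vegan``.  Each curve integrates
    to 1 on its grid.  A group with fewer than 2 entries is skipped with a
    warning when splitting, and raises :class:`DegenerateInputError` when it
    is the only group requested.
    """
    if lexicon.kind != "food":
        raise ValueError("nutrient_profile requires a food lexicon")
    if nutrient not in NUTRIENT_FIELDS:
        raise ValueError(f"nutrient must be one of {NUTRIENT_FIELDS}")

    groups: dict[str, np.ndarray]
    values = {k: getattr(e, nutrient) for k, e in lexicon.entries.items()}
    if split_vegan:
        groups = {
            "vegan": np.array([v for k, v in values.items() if lexicon.entries[k].is_vegan]),
            "non-vegan": np.array([v for k, v in values.items() if not lexicon.entries[k].is_vegan]),
        }
    else:
        groups = {"all": np.array(list(values.values()))}

    frames = []
    for name, vals in groups.items():
        if len(vals) < 2:
            if split_vegan:
                warnings.warn(f"group '{name}' has {len(vals)} entries; skipped in profile")
                continue
            raise DegenerateInputError(
                f"nutrient_profile needs at least 2 entries, got {len(vals)}"
            )
        grid, density = _kde_curve(vals)
        frames.append(pd.DataFrame({"group": name, "grid_value": grid, "density": density}))
    if not frames:
        raise DegenerateInputError("no group with at least 2 entries")
    return pd.concat(frames, ignore_index=True)
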