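"""Seeded synthetic post corpora with exact recorded ground truth.

The generator emulates a regional short-post corpus: each post is neutral
chatter into which food mentions, activity mentions and food-word idioms
are injected with configured probabilities, then roughened with natural
casing, stopword linkers, digits, hashtags and emoticons so the cleaning
pipeline is genuinely exercised.  Every injected mention is written to a
mention log, and the per-region ground-truth caloric values are computed
*from the log* — from what was actually emitted, not from the sampling
distribution — so recovery tests carry no Monte-Carlo tolerance.

Generation is fully deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .cleaning import RawPost, canonicalize
from .lexicon import Lexicon
from .phrases import PhraseInventory

__all__ = ["GeneratorConfig", "Mention", "GroundTruth", "generate_corpus", "verify_truth"]

_DEFAULT_CHATTER = (
    "weather", "morning", "meeting", "traffic", "weekend", "movie", "music",
    "project", "friend", "mood", "street", "window", "news", "garden",
    "laughter", "holiday", "sunshine", "evening", "moment", "story",
)
_STOPWORD_FILLER = ("I", "am", "the", "to", "my", "and", "of", "was", "so")
_EMOTICONS = (":-)", ":D", ";)", ":P")
_DIGIT_TOKENS = ("2", "4", "10", "2018", "2019")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a synthetic corpus.

    ``food_mix`` / ``activity_mix`` map surface phrases to mention
    probabilities (summing to 1); either one mix shared by all regions or a
    per-region mapping.  ``idiom_rate`` is the probability that a food slot
    carries a food-word idiom instead of a true food mention.
    """

    regions: tuple[str, ...]
    posts_per_region: int
    food_mix: Mapping
    activity_mix: Mapping
    idiom_rate: float = 0.0
    idiom_phrases: tuple[str, ...] = (
        "piece of cake",
        "apple of my eye",
        "bring home the bacon",
        "cup of tea",
        "couch potato",
    )
    chatter_vocab: tuple[str, ...] = _DEFAULT_CHATTER
    label_noise: float = 0.0
    p_food_post: float = 0.45
    p_activity_post: float = 0.35
    emoticon_rate: float = 0.2
    digit_rate: float = 0.15
    hashtag_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.posts_per_region < 0:
            raise ValueError("posts_per_region must be >= 0")
        for name in ("idiom_rate", "label_noise", "p_food_post", "p_activity_post"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def mix_for(self, which: str, region: str) -> dict[str, float]:
        mix = self.food_mix if which == "food" else self.activity_mix
        if mix and isinstance(next(iter(mix.values())), Mapping):
            mix = mix[region]
        out = {str(k): float(v) for k, v in mix.items()}
        total = sum(out.values())
        if not out or abs(total - 1.0) > 1e-6:
            raise ValueError(f"{which} mix for region '{region}' must sum to 1 (got {total})")
        return out


@dataclass(frozen=True)
class Mention:
    post_id: str
    region: str
    kind: str       # food | activity | idiom
    phrase: str     # canonical lexicon/inventory key


@dataclass
class GroundTruth:
    """Recorded truth of one generated corpus."""

    mention_log: tuple[Mention, ...]
    labels: dict[str, str]            # post id -> gold label (pre-noise)
    noisy_labels: dict[str, str]      # labels after label_noise flips
    c_in: dict[str, float | None]
    c_out: dict[str, float | None]
    c_rat: dict[str, float | None]

    def to_json(self) -> str:
        return json.dumps(
            {
                "mention_log": [vars(m) for m in self.mention_log],
                "labels": self.labels,
                "noisy_labels": self.noisy_labels,
                "c_in": self.c_in,
                "c_out": self.c_out,
                "c_rat": self.c_rat,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(
            mention_log=tuple(Mention(**m) for m in obj["mention_log"]),
            labels=obj["labels"],
            noisy_labels=obj["noisy_labels"],
            c_in=obj["c_in"],
            c_out=obj["c_out"],
            c_rat=obj["c_rat"],
        )


def _weighted_mean_from_counts(counts: dict[str, int], value_of) -> float | None:
    """Mention-weighted mean over sorted keys — the same aggregation order
    the caloric engine uses, so exact recovery implies float equality."""
    total = sum(counts.values())
    if total == 0:
        return None
    return sum(value_of(k) * f for k, f in sorted(counts.items())) / total


def truth_from_log(
    mention_log: Sequence[Mention],
    food_lexicon: Lexicon,
    activity_lexicon: Lexicon,
    regions: Sequence[str],
) -> tuple[dict, dict, dict]:
    """Per-region C_in / C_out / C_rat implied by a mention log."""
    c_in: dict[str, float | None] = {}
    c_out: dict[str, float | None] = {}
    c_rat: dict[str, float | None] = {}
    for region in regions:
        food_counts: dict[str, int] = {}
        act_counts: dict[str, int] = {}
        for m in mention_log:
            if m.region != region:
                continue
            if m.kind == "food":
                food_counts[m.phrase] = food_counts.get(m.phrase, 0) + 1
            elif m.kind == "activity":
                act_counts[m.phrase] = act_counts.get(m.phrase, 0) + 1
        ci = _weighted_mean_from_counts(food_counts, food_lexicon.caloric_value)
        co = _weighted_mean_from_counts(act_counts, activity_lexicon.caloric_value)
        c_in[region] = ci
        c_out[region] = co
        c_rat[region] = (ci / co) if (ci is not None and co is not None and co != 0) else None
    return c_in, c_out, c_rat


def _validate_phrases(
    config: GeneratorConfig,
    food_lexicon: Lexicon,
    activity_lexicon: Lexicon,
    idiom_inventory: PhraseInventory,
) -> dict[str, str]:
    """Check every mix/idiom phrase resolves in its lexicon; return the
    surface -> canonical-key mapping."""
    keymap: dict[str, str] = {}
    for region in config.regions:
        for which, lex in (("food", food_lexicon), ("activity", activity_lexicon)):
            for phrase in config.mix_for(which, region):
                key = " ".join(canonicalize(phrase))
                if key not in lex:
                    raise ValueError(f"{which} mix phrase '{phrase}' not in {which} lexicon")
                keymap[phrase] = key
    idioms = idiom_inventory.subset("idiom") if any(
        t != "idiom" for t in idiom_inventory.forms.values()
    ) else idiom_inventory
    if config.idiom_rate > 0:
        for phrase in config.idiom_phrases:
            form = canonicalize(phrase)
            if form not in idioms:
                raise ValueError(f"idiom phrase '{phrase}' not in idiom inventory")
            keymap[phrase] = " ".join(form)
    return keymap


def _sampler(mix: dict[str, float]):
    phrases = sorted(mix)
    probs = np.array([mix[p] for p in phrases])
    probs = probs / probs.sum()
    return phrases, probs


def _render_post(rng: np.random.Generator, config: GeneratorConfig, insertions: list[str]) -> str:
    """Assemble one post: shuffled chatter + contiguous phrase insertions,
    roughened with casing, stopword linkers, hashtags, digits, emoticons."""
    n_chatter = 2 + int(rng.poisson(4))
    units: list[list[str]] = [
        [str(rng.choice(config.chatter_vocab))] for _ in range(n_chatter)
    ]
    units.extend([phrase.split() for phrase in insertions])
    order = rng.permutation(len(units))
    words: list[str] = []
    for u in order:
        if words and rng.random() < 0.3:
            words.append(str(rng.choice(_STOPWORD_FILLER)))
        if rng.random() < config.digit_rate:
            words.append(str(rng.choice(_DIGIT_TOKENS)))
        unit = list(units[u])
        if len(unit) == 1 and rng.random() < config.hashtag_rate:
            unit[0] = "#" + unit[0]
        for w in unit:
            if rng.random() < 0.1:
                w = w.capitalize()
            words.append(w)
    if words and rng.random() < 0.5:
        words[0] = words[0].capitalize()
    if rng.random() < config.emoticon_rate:
        words.append(str(rng.choice(_EMOTICONS)))
    return " ".join(words)


def generate_corpus(
    config: GeneratorConfig,
    food_lexicon: Lexicon,
    activity_lexicon: Lexicon,
    idiom_inventory: PhraseInventory | None = None,
) -> tuple[list[RawPost], GroundTruth]:
    """Generate a regional corpus plus its exact ground truth.

    Raises ``ValueError`` when a mix references a phrase missing from its
    lexicon or inventory.
    """
    idiom_inventory = idiom_inventory if idiom_inventory is not None else PhraseInventory.gold()
    keymap = _validate_phrases(config, food_lexicon, activity_lexicon, idiom_inventory)
    rng = np.random.default_rng(config.seed)

    posts: list[RawPost] = []
    log: list[Mention] = []
    labels: dict[str, str] = {}
    noisy: dict[str, str] = {}
    for region in config.regions:
        food_phrases, food_p = _sampler(config.mix_for("food", region))
        act_phrases, act_p = _sampler(config.mix_for("activity", region))
        for i in range(config.posts_per_region):
            pid = f"{region}-{i:06d}"
            insertions: list[str] = []
            has_food = False
            if rng.random() < config.p_food_post:
                if config.idiom_rate > 0 and rng.random() < config.idiom_rate:
                    phrase = str(rng.choice(config.idiom_phrases))
                    log.append(Mention(pid, region, "idiom", keymap[phrase]))
                else:
                    phrase = str(food_phrases[rng.choice(len(food_phrases), p=food_p)])
                    log.append(Mention(pid, region, "food", keymap[phrase]))
                    has_food = True
                insertions.append(phrase)
            if rng.random() < config.p_activity_post:
                phrase = str(act_phrases[rng.choice(len(act_phrases), p=act_p)])
                log.append(Mention(pid, region, "activity", keymap[phrase]))
                insertions.append(phrase)
            text = _render_post(rng, config, insertions)
            minute = len(posts)
            timestamp = f"2018-06-01T{(minute // 60) % 24:02d}:{minute % 60:02d}:00"
            posts.append(RawPost(id=pid, text=text, region=region, timestamp=timestamp))
            gold = "food" if has_food else "non-food"
            labels[pid] = gold
            if config.label_noise > 0 and rng.random() < config.label_noise:
                noisy[pid] = "non-food" if gold == "food" else "food"
            else:
                noisy[pid] = gold

    c_in, c_out, c_rat = truth_from_log(log, food_lexicon, activity_lexicon, config.regions)
    truth = GroundTruth(
        mention_log=tuple(log),
        labels=labels,
        noisy_labels=noisy,
        c_in=c_in,
        c_out=c_out,
        c_rat=c_rat,
    )
    return posts, truth


def verify_truth(
    truth: GroundTruth,
    food_lexicon: Lexicon,
    activity_lexicon: Lexicon,
    rel_tol: float = 1e-12,
) -> bool:
    """True iff the stored truths equal a brute-force per-mention
    recomputation from the mention log.

    The oracle here is the naive per-mention average (sum of each single
    mention's caloric value divided by the number of mentions), evaluated
    independently of the engine's count-weighted formula.
    """
    regions = sorted({*truth.c_in, *truth.c_out})
    for region in regions:
        for kind, lex, stored in (
            ("food", food_lexicon, truth.c_in.get(region)),
            ("activity", activity_lexicon, truth.c_out.get(region)),
        ):
            values = [
                lex.caloric_value(m.phrase)
                for m in truth.mention_log
                if m.region == region and m.kind == kind
            ]
            if not values:
                if stored is not None:
                    return False
                continue
            oracle = sum(values) / len(values)
            if stored is None:
                return False
            scale = max(abs(oracle), 1.0)
            if abs(stored - oracle) > rel_tol * scale:
                return False
        ci, co, cr = truth.c_in.get(region), truth.c_out.get(region), truth.c_rat.get(region)
        if ci is None or co is None or co == 0:
            if cr is not None:
                return False
        elif cr is None or abs(cr - ci / co) > rel_tol * max(abs(cr), 1.0):
            return False
    return True
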