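"""Caloric engine: oracle equivalence, invariants, aggregation, shares."""

from __future__ import annotations

import numpy as np
import pytest

from calotext.calorics import (
    CaloricSummary,
    EngineConfig,
    FrequencyTable,
    caloric_burn,
    caloric_intake,
    caloric_ratio,
    count_mentions,
    population_share_above,
    read_populations,
    regional_summary,
    summary_frame,
    top_k,
)
from calotext.cleaning import CleanPost, RawPost, clean
from calotext.errors import SchemaError, UndefinedCaloricResult
from calotext.lexicon import load_food_lexicon
from calotext.phrases import PhraseInventory


def posts_from_texts(texts, region="all"):
    return [clean(RawPost(id=f"{region}-{i}", text=t, region=region)) for i, t in enumerate(texts)]


def per_mention_oracle(mentions, values):
    """Brute force: average caloric value over the flat list of mentions."""
    vals = [values[m] for m in mentions]
    return sum(vals) / len(vals)


class TestCaloricIntake:
    def test_constant_food_mean_is_value(self, food_lexicon):
        posts = posts_from_texts(["pizza again"] * 4)
        c_in, table = caloric_intake(posts, food_lexicon)
        assert c_in == 266 and table.counts == {"pizza": 4}

    def test_weighted_mean_matches_hand_oracle(self, tmp_path):
        path = tmp_path / "food.csv"
        path.write_text(
            "food_name,food_ingredients,fat_100g,energy_100g,carbohydrate_100g\n"
            "soup,,1,100,5\nsteak,,20,300,0\n"
        )
        lex = load_food_lexicon(path)
        posts = posts_from_texts(["soup", "steak", "steak", "steak"])
        c_in, _ = caloric_intake(posts, lex)
        assert c_in == per_mention_oracle(["soup", "steak", "steak", "steak"], {"soup": 100, "steak": 300}) == 250

    def test_only_masked_mentions_is_undefined(self, food_lexicon, gold_inventory):
        posts = posts_from_texts(["the test was a piece of cake", "not my cup of tea"])
        with pytest.raises(UndefinedCaloricResult):
            caloric_intake(posts, food_lexicon, gold_inventory)

    def test_mask_soundness_masked_tokens_never_counted(self, food_lexicon, gold_inventory):
        base = posts_from_texts(["pizza and coffee", "tea first"])
        c_in0, t0 = caloric_intake(base, food_lexicon, gold_inventory)
        extra = base + posts_from_texts(["it was a piece of cake honestly", "bring home the bacon"], region="x")
        c_in1, t1 = caloric_intake(extra, food_lexicon, gold_inventory)
        assert c_in1 == c_in0 and t1.counts == t0.counts


class TestCaloricBurn:
    def test_constant_activity(self, activity_lexicon):
        posts = posts_from_texts(["went running", "running again"])
        c_out, table = caloric_burn(posts, activity_lexicon)
        assert c_out == 600 and table.counts == {"running": 2}

    def test_weighted_mean(self, activity_lexicon):
        posts = posts_from_texts(["walking", "walking", "running", "running"])
        c_out, _ = caloric_burn(posts, activity_lexicon)
        assert c_out == per_mention_oracle(
            ["walking", "walking", "running", "running"], {"walking": 200, "running": 600}
        ) == 400

    def test_subject_weight_scales_linearly(self, activity_lexicon):
        posts = posts_from_texts(["running"])
        config = EngineConfig(reference_weight=80.7, subject_weight=2 * 80.7)
        c_out, _ = caloric_burn(posts, activity_lexicon, config)
        assert c_out == 1200

    def test_no_activity_mentions_undefined(self, activity_lexicon):
        with pytest.raises(UndefinedCaloricResult):
            caloric_burn(posts_from_texts(["nothing relevant"]), activity_lexicon)


class TestCaloricRatio:
    def test_quotients(self):
        assert caloric_ratio(2000, 1000) == 2.0
        assert caloric_ratio(250, 400) == 0.625
        for x in (0.1, 1.0, 3500.0):
            assert caloric_ratio(x, x) == 1.0

    def test_undefined_signalled(self):
        with pytest.raises(UndefinedCaloricResult):
            caloric_ratio(100.0, 0.0)
        with pytest.raises(UndefinedCaloricResult):
            caloric_ratio(None, 100.0)


def test_oracle_equivalence_on_random_corpora(food_lexicon, activity_lexicon):
    """c_in / c_out equal the brute-force per-mention average to <= 1e-9
    relative error on many random synthetic mention corpora."""
    rng = np.random.default_rng(20240915)
    foods = sorted(food_lexicon.keys())
    acts = sorted(activity_lexicon.keys())
    food_vals = {k: food_lexicon.caloric_value(k) for k in foods}
    act_vals = {k: activity_lexicon.caloric_value(k) for k in acts}
    for _ in range(300):
        n = int(rng.integers(1, 30))
        mentions_f = [foods[i] for i in rng.integers(0, len(foods), n)]
        mentions_a = [acts[i] for i in rng.integers(0, len(acts), n)]
        posts = posts_from_texts(mentions_f + mentions_a)
        c_in, _ = caloric_intake(posts, food_lexicon)
        c_out, _ = caloric_burn(posts, activity_lexicon)
        assert c_in == pytest.approx(per_mention_oracle(mentions_f, food_vals), rel=1e-9)
        assert c_out == pytest.approx(per_mention_oracle(mentions_a, act_vals), rel=1e-9)


def test_boundedness_and_scale_equivariance(tmp_path, activity_lexicon):
    header = "food_name,food_ingredients,fat_100g,energy_100g,carbohydrate_100g\n"
    (tmp_path / "f1.csv").write_text(header + "soup,,1,100,5\nsteak,,20,300,0\n")
    (tmp_path / "f3.csv").write_text(header + "soup,,1,300,5\nsteak,,20,900,0\n")
    lex1 = load_food_lexicon(tmp_path / "f1.csv")
    lex3 = load_food_lexicon(tmp_path / "f3.csv")
    posts = posts_from_texts(["soup and steak", "steak"])
    c1, _ = caloric_intake(posts, lex1)
    c3, _ = caloric_intake(posts, lex3)
    assert 100 <= c1 <= 300
    assert c3 == pytest.approx(3 * c1, rel=1e-12)
    c_out, _ = caloric_burn(posts_from_texts(["running", "walking"]), activity_lexicon)
    assert caloric_ratio(c3, c_out) == pytest.approx(3 * caloric_ratio(c1, c_out), rel=1e-12)


class TestRegionalSummary:
    def test_per_region_matches_hand_values(self, food_lexicon, activity_lexicon):
        posts = (
            posts_from_texts(["pizza", "pizza", "running"], region="ON")
            + posts_from_texts(["coffee", "walking", "walking"], region="QC")
        )
        summaries = regional_summary(posts, food_lexicon, activity_lexicon)
        assert summaries["ON"].c_rat == pytest.approx(266 / 600)
        assert summaries["QC"].c_rat == pytest.approx(1 / 200)
        assert summaries["ON"].n_food_mentions == 2

    def test_region_without_activity_flagged(self, food_lexicon, activity_lexicon):
        posts = posts_from_texts(["pizza"], region="NU")
        summaries = regional_summary(posts, food_lexicon, activity_lexicon)
        assert summaries["NU"].c_rat is None
        assert summaries["NU"].flag == "undefined-ratio"

    def test_single_region_equals_corpus_level(self, food_lexicon, activity_lexicon):
        posts = posts_from_texts(["pizza and running", "coffee walking"], region="AB")
        summaries = regional_summary(posts, food_lexicon, activity_lexicon)
        c_in, _ = caloric_intake(posts, food_lexicon)
        c_out, _ = caloric_burn(posts, activity_lexicon)
        assert summaries["AB"].c_in == c_in and summaries["AB"].c_out == c_out

    def test_min_mentions_flags_insufficient(self, food_lexicon, activity_lexicon):
        posts = posts_from_texts(["pizza running"], region="YT")
        config = EngineConfig(min_mentions_per_region=5)
        summaries = regional_summary(posts, food_lexicon, activity_lexicon, config)
        assert summaries["YT"].flag == "insufficient" and summaries["YT"].c_rat is None

    def test_aggregation_consistency(self, food_lexicon, activity_lexicon):
        """Pooling all regions equals the mention-weighted combination of
        per-region tables."""
        posts = (
            posts_from_texts(["pizza", "cake cake? cake!"], region="ON")
            + posts_from_texts(["coffee", "pizza"], region="QC")
        )
        pooled = count_mentions(posts, food_lexicon)
        combined: dict[str, int] = {}
        for region in ("ON", "QC"):
            t = count_mentions([p for p in posts if p.region == region], food_lexicon)
            for k, v in t.counts.items():
                combined[k] = combined.get(k, 0) + v
        assert pooled.counts == combined


class TestTopK:
    def test_orders_by_count(self):
        table = FrequencyTable(counts={"coffee": 5, "tea": 3})
        assert top_k(table, 10) == [("coffee", 5), ("tea", 3)]

    def test_tie_breaks_lexicographically(self):
        table = FrequencyTable(counts={"b": 2, "a": 2})
        assert top_k(table, 1) == [("a", 2)]

    def test_agrees_with_full_sort_oracle(self):
        rng = np.random.default_rng(7)
        counts = {f"p{i:02d}": int(rng.integers(1, 40)) for i in range(50)}
        table = FrequencyTable(counts=counts)
        oracle = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        assert top_k(table, 50) == oracle
        assert top_k(table, 7) == oracle[:7]

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            top_k(FrequencyTable(counts={"a": 1}), 0)


def summary(region, c_rat):
    return CaloricSummary(
        scope=region, c_in=None, c_out=None, c_rat=c_rat,
        n_food_mentions=0, n_activity_mentions=0,
    )


class TestPopulationShare:
    def test_all_above(self):
        s = {"A": summary("A", 1.5), "B": summary("B", 2.0)}
        assert population_share_above(s, {"A": 10, "B": 30}) == 100.0

    def test_none_above(self):
        s = {"A": summary("A", 0.5), "B": summary("B", 0.9)}
        assert population_share_above(s, {"A": 10, "B": 30}) == 0.0

    def test_direct_proportion(self):
        s = {"A": summary("A", 1.2), "B": summary("B", 0.8)}
        assert population_share_above(s, {"A": 60, "B": 40}) == 60.0

    def test_missing_population_is_error(self):
        s = {"A": summary("A", 1.2)}
        with pytest.raises(SchemaError, match="A"):
            population_share_above(s, {})

    def test_undefined_regions_excluded(self):
        s = {"A": summary("A", 1.2), "B": summary("B", None)}
        assert population_share_above(s, {"A": 10}) == 100.0


def test_summary_frame_header(food_lexicon, activity_lexicon):
    posts = posts_from_texts(["pizza running"], region="ON")
    df = summary_frame(regional_summary(posts, food_lexicon, activity_lexicon))
    assert list(df.columns) == [
        "region", "c_in", "c_out", "c_rat", "n_food_mentions", "n_activity_mentions", "flag",
    ]


def test_read_populations(tmp_path):
    path = tmp_path / "pop.csv"
    path.write_text("region,population\nON,100\nQC,60\n")
    assert read_populations(path) == {"ON": 100.0, "QC": 60.0}
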