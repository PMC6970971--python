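"""Shared fixtures: fixture-scale lexicons and the packaged inventory.

All fixture data is generated programmatically; nothing is read from
outside the repository.
"""

from __future__ import annotations

import pytest

from calotext.lexicon import Lexicon, load_activity_lexicon, load_food_lexicon
from calotext.phrases import PhraseInventory

FOOD_CSV = """food_name,food_ingredients,fat_100g,energy_100g,carbohydrate_100g
pizza,flour;cheese;tomato,10,266,33
coffee,coffee beans,0,1,0
cake,flour;sugar;butter,15,350,55
burger,beef;bun,12,295,24
noodles,wheat,5,138,25
tea,tea leaves,0,1,0
sweet potato,sweet potato,0.1,86,20
orange juice,orange,0.2,45,10
vegan burger,soy;bun,8,230,25
chicken masala,chicken;spices,9,180,6
mango,mango,0.4,60,15
pie,flour;fruit,14,260,34
"""

ACTIVITY_CSV = """activity_name,caloric_value
running,600
walking,200
reading,50
swimming,500
cooking,150
skiing,450
"""


@pytest.fixture(scope="session")
def food_csv(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("lex") / "food.csv"
    path.write_text(FOOD_CSV, encoding="utf-8")
    return str(path)


@pytest.fixture(scope="session")
def activity_csv(tmp_path_factory) -> str:
    path = tmp_path_factory.mktemp("lex") / "activity.csv"
    path.write_text(ACTIVITY_CSV, encoding="utf-8")
    return str(path)


@pytest.fixture(scope="session")
def food_lexicon(food_csv) -> Lexicon:
    return load_food_lexicon(food_csv)


@pytest.fixture(scope="session")
def activity_lexicon(activity_csv) -> Lexicon:
    return load_activity_lexicon(activity_csv)


@pytest.fixture(scope="session")
def gold_inventory() -> PhraseInventory:
    return PhraseInventory.gold()
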