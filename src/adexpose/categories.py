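"""Food category codes and the fine-to-coarse category map.

The advertising data use 57 fine product categories which are aggregated
into 13 coarse categories for reporting. The map is total (every fine code
has exactly one coarse code) and surjective onto the 13 coarse codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CategoryError, ValidationError

#: The 13 coarse reporting categories, in table order.
COARSE_CATEGORIES: tuple[str, ...] = (
    "bread",
    "sweet_baked_goods_desserts",
    "candy_and_chocolate",
    "breakfast_food",
    "dairy",
    "condiments",
    "entrees",
    "fruits_vegetables",
    "beverages",
    "miscellaneous",
    "snacks",
    "water",
    "restaurants",
)

# 57 fine codes grouped by coarse category.
_FINE_BY_COARSE: dict[str, tuple[str, ...]] = {
    "bread": ("white_bread", "whole_grain_bread", "bagels_buns"),
    "sweet_baked_goods_desserts": (
        "cakes", "cookies", "pastries", "doughnuts", "frozen_desserts",
    ),
    "candy_and_chocolate": (
        "chocolate_bars", "gummy_candy", "hard_candy", "gum_mints", "seasonal_candy",
    ),
    "breakfast_food": (
        "cold_cereal", "hot_cereal", "granola_cereal_bars", "toaster_pastries",
    ),
    "dairy": (
        "milk", "flavoured_milk", "yogurt", "cheese", "ice_cream", "dairy_alternatives",
    ),
    "condiments": (
        "ketchup_mustard", "salad_dressing", "sauces_gravies", "spreads_dips",
    ),
    "entrees": (
        "frozen_entrees", "canned_entrees", "pizza", "processed_meat",
        "fresh_meat_poultry", "fish_seafood",
    ),
    "fruits_vegetables": (
        "fresh_fruit", "fresh_vegetables", "canned_frozen_fruit",
        "canned_frozen_vegetables",
    ),
    "beverages": (
        "regular_soft_drinks", "diet_soft_drinks", "fruit_juice", "fruit_drinks",
        "sports_energy_drinks", "coffee_tea",
    ),
    "miscellaneous": ("meal_kits", "soups", "baking_ingredients", "baby_food"),
    "snacks": (
        "potato_chips", "crackers", "popcorn_pretzels", "nuts_seeds", "fruit_snacks",
    ),
    "water": ("plain_water", "sparkling_flavoured_water"),
    "restaurants": ("fast_food_restaurants", "sit_down_restaurants", "coffee_shops"),
}

#: Default fine -> coarse mapping covering all 57 fine codes.
DEFAULT_CATEGORY_ENTRIES: dict[str, str] = {
    fine: coarse for coarse, fines in _FINE_BY_COARSE.items() for fine in fines
}

FINE_CATEGORIES: tuple[str, ...] = tuple(DEFAULT_CATEGORY_ENTRIES)

assert len(FINE_CATEGORIES) == 57


@dataclass(frozen=True)
class CategoryMap:
    """A total mapping from fine product-category codes to coarse codes."""

    entries: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_ENTRIES)
    )

    def __post_init__(self) -> None:
        bad = sorted(set(self.entries.values()) - set(COARSE_CATEGORIES))
        if bad:
            raise ValidationError(f"unknown coarse categories in map: {bad}")

    def coarse(self, fine_code: str) -> str:
        try:
            return self.entries[fine_code]
        except KeyError:
            raise CategoryError(
                f"fine category {fine_code!r} has no coarse mapping"
            ) from None

    def covers(self, fine_codes: Iterable[str]) -> bool:
        return set(fine_codes) <= set(self.entries)

    @property
    def is_surjective(self) -> bool:
        return set(self.entries.values()) == set(COARSE_CATEGORIES)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.entries.items()), columns=["fine_code", "coarse_code"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CategoryMap":
        df = pd.read_csv(path, dtype=str)
        missing = {"fine_code", "coarse_code"} - set(df.columns)
        if missing:
            raise ValidationError(f"category map missing columns: {sorted(missing)}")
        return cls(dict(zip(df["fine_code"], df["coarse_code"])))


DEFAULT_CATEGORY_MAP = CategoryMap()
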