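"""Nutrient-profile classification of products and advertisements.

Products are looked up through a provenance-tiered cascade of nutrition
tables (packaged-food database first, restaurant-menu database for
restaurant items, then progressively weaker web sources). A product is
"unhealthy" when any nutrient it contains as an added ingredient strictly
exceeds its configured threshold; an advertisement is unhealthy when any of
its classifiable products is. Threshold values are configuration, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import NutritionError, ValidationError
from .ingest import UniqueAd

#: Nutrients tracked on a profile, with units baked into the key.
NUTRIENTS: tuple[str, ...] = ("fat_g", "saturated_fat_g", "sugars_g", "sodium_mg")

#: Which added-ingredient flag governs each nutrient.
ADDED_FLAG_FOR: dict[str, str] = {
    "fat_g": "fat",
    "saturated_fat_g": "fat",
    "sugars_g": "sugar",
    "sodium_mg": "sodium",
}

#: Lookup cascade order, strongest provenance first.
SOURCE_TIERS: tuple[str, ...] = (
    "flip_2017",
    "menu_flip_2016",
    "company_ca_site",
    "nft_online",
    "company_us_site",
    "cnf_substitute",
)

BASES = ("per_serving", "per_reference_amount")

HEALTHY = "healthy"
UNHEALTHY = "unhealthy"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient amounts for one product, with source provenance."""

    product_id: str
    basis: str = "per_serving"
    amounts: Mapping[str, float] = field(default_factory=dict)
    contains_added: Mapping[str, bool] = field(default_factory=dict)
    source_tier: Optional[str] = None
    missing: bool = False

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValidationError(f"unknown basis {self.basis!r}")
        if self.missing and self.amounts:
            raise ValidationError("missing profile must not carry amounts")
        for k, v in self.amounts.items():
            if v < 0:
                raise ValidationError(f"negative amount for {k}: {v}")


@dataclass(frozen=True)
class ThresholdConfig:
    """Nutrient exceedance limits; rule is any-exceed with strict inequality."""

    thresholds: Mapping[str, float]
    basis: str = "per_serving"
    rule: str = "any-exceed"

    def __post_init__(self) -> None:
        if self.basis not in BASES:
            raise ValidationError(f"unknown basis {self.basis!r}")
        for k, v in self.thresholds.items():
            if v <= 0:
                raise ValidationError(f"threshold for {k} must be positive, got {v}")


#: Fixture threshold set used by the synthetic market and tests. The real
#: regulatory limits belong in a versioned config file, not in code.
DEFAULT_THRESHOLDS = ThresholdConfig(
    thresholds={
        "fat_g": 3.0,
        "saturated_fat_g": 2.0,
        "sugars_g": 5.0,
        "sodium_mg": 200.0,
    },
    basis="per_serving",
)


def load_thresholds(path: str | Path) -> ThresholdConfig:
    """Load a ThresholdConfig from YAML or JSON."""
    data = yaml.safe_load(Path(path).read_text())
    return ThresholdConfig(
        thresholds={str(k): float(v) for k, v in data["thresholds"].items()},
        basis=data.get("basis", "per_serving"),
        rule=data.get("rule", "any-exceed"),
    )


def _profile_from_row(row: pd.Series, tier: str) -> NutrientProfile:
    amounts = {}
    for nut in NUTRIENTS:
        if nut in row.index and pd.notna(row[nut]):
            val = float(row[nut])
            if val < 0:
                raise NutritionError(
                    f"malformed nutrition row for {row['product_id']}: {nut} < 0"
                )
            amounts[nut] = val
    contains = {
        flag: bool(row.get(f"added_{flag}", False))
        for flag in ("fat", "sugar", "sodium")
    }
    basis = row.get("basis", "per_serving")
    if pd.isna(basis):
        raise NutritionError(f"malformed nutrition row for {row['product_id']}: no basis")
    return NutrientProfile(
        product_id=str(row["product_id"]),
        basis=str(basis),
        amounts=amounts,
        contains_added=contains,
        source_tier=tier,
    )


def lookup_nutrition(
    product_id: str,
    sources: Sequence[tuple[str, pd.DataFrame]],
) -> NutrientProfile:
    """Resolve a product through the tiered source cascade.

    ``sources`` is an ordered sequence of (tier name, table); the first table
    containing the product wins and its tier is recorded on the profile. A
    product present nowhere yields a profile with ``missing=True``.
    """
    for tier, table in sources:
        hit = table.loc[table["product_id"] == product_id]
        if len(hit):
            return _profile_from_row(hit.iloc[0], tier)
    return NutrientProfile(product_id=product_id, missing=True)


def classify_product(profile: NutrientProfile, config: ThresholdConfig) -> str:
    """Label one product healthy/unhealthy under the any-exceed rule.

    Exceedance is strict: an amount exactly at the limit is compliant. Only
    nutrients whose added-ingredient flag is set can trigger exceedance.
    """
    if profile.missing:
        raise NutritionError(f"cannot classify missing profile {profile.product_id}")
    if profile.basis != config.basis:
        raise NutritionError(
            f"basis mismatch for {profile.product_id}: "
            f"profile {profile.basis} vs thresholds {config.basis}"
        )
    for nutrient, limit in config.thresholds.items():
        flag = ADDED_FLAG_FOR.get(nutrient)
        if flag is None or not profile.contains_added.get(flag, False):
            continue
        amount = profile.amounts.get(nutrient)
        if amount is not None and amount > limit:
            return UNHEALTHY
    return HEALTHY


def classify_ad(ad: UniqueAd, product_labels: Mapping[str, str]) -> str:
    """Aggregate product labels to the advertisement level.

    Unhealthy if any constituent product is unhealthy; healthy if at least
    one product is classifiable and none is unhealthy; unclassified for
    brand ads or when every product profile is missing. All products count,
    including any beyond the 3-product weighting cap.
    """
    labels = [
        product_labels.get(p.product_id, UNCLASSIFIED) for p in ad.products
    ]
    classifiable = [l for l in labels if l in (HEALTHY, UNHEALTHY)]
    if not classifiable:
        return UNCLASSIFIED
    if UNHEALTHY in classifiable:
        return UNHEALTHY
    return HEALTHY


def classify_products(
    products: pd.DataFrame, config: ThresholdConfig
) -> dict[str, str]:
    """Classify every row of a flat nutrition table (see ``read_nutrition_csv``)."""
    labels: dict[str, str] = {}
    for _, row in products.iterrows():
        if bool(row.get("missing", False)):
            continue
        labels[str(row["product_id"])] = classify_product(
            _profile_from_row(row, str(row.get("source_tier", "flip_2017"))), config
        )
    return labels


def healthfulness_shares(frequency_by_label: Mapping[str, float]) -> dict[str, float]:
    """Healthy/unhealthy shares over classified weighted frequency.

    The denominator excludes unclassified ads; shares sum to 100.

    >>> healthfulness_shares({"healthy": 74617, "unhealthy": 783855})
    {'healthy': 8.7, 'unhealthy': 91.3}
    """
    healthy = float(frequency_by_label.get(HEALTHY, 0.0))
    unhealthy = float(frequency_by_label.get(UNHEALTHY, 0.0))
    total = healthy + unhealthy
    if total <= 0:
        raise NutritionError("no classified advertisements: shares undefined")
    from .report import round_half_up

    return {
        HEALTHY: round_half_up(healthy / total * 100.0, 1),
        UNHEALTHY: round_half_up(unhealthy / total * 100.0, 1),
    }


def read_nutrition_csv(path: str | Path) -> pd.DataFrame:
    """Read a flat nutrition table (one row per product, tier column)."""
    df = pd.read_csv(path, dtype={"product_id": str, "source_tier": str, "basis": str})
    if "product_id" not in df.columns:
        raise NutritionError("nutrition table missing product_id column")
    return df


def nutrition_sources(products: pd.DataFrame) -> list[tuple[str, pd.DataFrame]]:
    """Split a flat nutrition table into the ordered cascade of tier tables."""
    out = []
    for tier in SOURCE_TIERS:
        sub = products.loc[products.get("source_tier") == tier]
        if len(sub):
            out.append((tier, sub))
    return out
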