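"""Advertising data model, deduplication and weighted frequency.

An occurrence log records every airing (station, timestamp, ad id); the
unique-ad file describes each distinct creative and its featured products.
Two creatives are the same unique ad only if they agree on content, language
and duration. The weighted frequency of an ad multiplies its airings by its
product count, capped at 3 products; brand ads (no identifiable product)
carry one creative unit per airing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .categories import CategoryMap
from .errors import IngestError, ValidationError

#: Product count above which additional products stop adding weight.
PRODUCT_CAP = 3


@dataclass(frozen=True)
class Product:
    """One identifiable food product featured in an advertisement."""

    product_id: str
    name: str
    fine_category: str


@dataclass(frozen=True)
class UniqueAd:
    """One distinct creative.

    Identity is the triple (content_key, language, duration); two records
    differing in any of the three are distinct unique ads. ``techniques``
    holds the consensus presence map once the ad has been coded.
    """

    ad_id: str
    content_key: str
    language: str
    duration: int  # seconds
    products: tuple[Product, ...] = ()
    techniques: Optional[Mapping[str, bool]] = None

    @property
    def identity(self) -> tuple[str, str, int]:
        return (self.content_key, self.language, self.duration)

    @property
    def n_products(self) -> int:
        # unique products: listing the same product twice adds no weight
        return len({p.product_id for p in self.products})

    @property
    def is_brand_ad(self) -> bool:
        return not self.products

    def coarse_categories(self, catmap: CategoryMap) -> tuple[str, ...]:
        """Distinct coarse categories touched by this ad, in product order."""
        seen: dict[str, None] = {}
        for p in self.products:
            seen.setdefault(catmap.coarse(p.fine_category), None)
        return tuple(seen)


@dataclass(frozen=True)
class AdOccurrence:
    """One airing event of a unique ad on a station."""

    station: str
    start: pd.Timestamp
    ad_id: str


def product_weight(n_products: int) -> int:
    """Per-airing weight of an ad: product count capped at 3, brand ads 1."""
    if n_products < 0:
        raise ValidationError(f"n_products must be >= 0, got {n_products}")
    return min(max(n_products, 1), PRODUCT_CAP)


def weighted_frequency(n_products: int, n_airings: int) -> int:
    """Weighted frequency = capped product count x airings.

    >>> weighted_frequency(2, 500)
    1000
    >>> weighted_frequency(4, 500)
    1500
    """
    if n_airings < 0:
        raise ValidationError(f"n_airings must be >= 0, got {n_airings}")
    return product_weight(n_products) * n_airings


def dedupe_unique_ads(raw_ads: Sequence[UniqueAd]) -> list[UniqueAd]:
    """Collapse candidate records to one representative per identity triple.

    Stable: the first occurrence of each (content_key, language, duration)
    wins. A record with a missing identity field is rejected with its index.
    """
    seen: dict[tuple[str, str, int], UniqueAd] = {}
    for i, ad in enumerate(raw_ads):
        if not ad.content_key or not ad.language or ad.duration is None:
            raise IngestError(f"record {i}: missing identity field (content/language/duration)")
        seen.setdefault(ad.identity, ad)
    return list(seen.values())


def frequency_table(
    airings: pd.DataFrame,
    ads: Mapping[str, UniqueAd],
    catmap: CategoryMap,
) -> pd.DataFrame:
    """Weighted frequency by coarse category, with percent of grand total.

    Convention: an ad spanning several coarse categories contributes its full
    weighted frequency to each category row, but only once to the grand
    total, so category rows can sum to more than the total. The percent
    column uses the deduplicated grand total as denominator. Brand ads count
    one unit per airing in the total and are absent from category rows.

    Returns a DataFrame indexed by coarse category with columns
    ``weighted_frequency`` and ``percent``; the deduplicated grand total is
    stored in ``.attrs["total"]`` and the brand-ad contribution in
    ``.attrs["brand_weighted_frequency"]``.
    """
    counts = airings["ad_id"].value_counts()
    unknown = [a for a in counts.index if a not in ads]
    if unknown:
        raise IngestError(f"airings reference unknown ad ids: {sorted(unknown)[:5]}")

    by_cat: dict[str, int] = {}
    total = 0
    brand_total = 0
    for ad_id, n_airings in counts.items():
        ad = ads[ad_id]
        wf = weighted_frequency(ad.n_products, int(n_airings))
        total += wf
        if ad.is_brand_ad:
            brand_total += wf
            continue
        for cat in ad.coarse_categories(catmap):
            by_cat[cat] = by_cat.get(cat, 0) + wf

    from .categories import COARSE_CATEGORIES

    rows = [c for c in COARSE_CATEGORIES if c in by_cat]
    table = pd.DataFrame(
        {
            "weighted_frequency": [by_cat[c] for c in rows],
        },
        index=pd.Index(rows, name="coarse_category"),
    )
    table["percent"] = (
        table["weighted_frequency"] / total * 100.0 if total else 0.0
    )
    table.attrs["total"] = total
    table.attrs["brand_weighted_frequency"] = brand_total
    return table


# ---------------------------------------------------------------------------
# On-disk formats: occurrence log CSV, unique-ad JSON.
# ---------------------------------------------------------------------------

AIRINGS_COLUMNS = ("station", "start_iso8601", "ad_id")


def read_airings_csv(path: str | Path) -> pd.DataFrame:
    """Read an occurrence log; returns columns station, start, ad_id."""
    df = pd.read_csv(path, dtype={"station": str, "ad_id": str})
    missing = set(AIRINGS_COLUMNS) - set(df.columns)
    if missing:
        raise IngestError(f"occurrence log missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "station": df["station"],
            "start": pd.to_datetime(df["start_iso8601"]),
            "ad_id": df["ad_id"],
        }
    )
    return out


def write_airings_csv(airings: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "station": airings["station"],
            "start_iso8601": pd.to_datetime(airings["start"]).dt.strftime(
                "%Y-%m-%dT%H:%M:%S"
            ),
            "ad_id": airings["ad_id"],
        }
    )
    out.to_csv(path, index=False)


def ads_to_json(ads: Iterable[UniqueAd], path: str | Path) -> None:
    records = []
    for ad in ads:
        records.append(
            {
                "ad_id": ad.ad_id,
                "content_key": ad.content_key,
                "language": ad.language,
                "duration": ad.duration,
                "products": [
                    {
                        "product_id": p.product_id,
                        "name": p.name,
                        "fine_category": p.fine_category,
                    }
                    for p in ad.products
                ],
                "techniques": dict(ad.techniques) if ad.techniques is not None else None,
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def ads_from_json(path: str | Path) -> dict[str, UniqueAd]:
    records = json.loads(Path(path).read_text())
    ads: dict[str, UniqueAd] = {}
    for r in records:
        ads[r["ad_id"]] = UniqueAd(
            ad_id=r["ad_id"],
            content_key=r["content_key"],
            language=r["language"],
            duration=int(r["duration"]),
            products=tuple(
                Product(p["product_id"], p["name"], p["fine_category"])
                for p in r["products"]
            ),
            techniques=r.get("techniques"),
        )
    return ads
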