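"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import pandas as pd
import pytest

from adexpose.ingest import Product, UniqueAd, product_weight
from adexpose.simulate import MarketConfig, generate_market

TINY_POP = {
    "child_2_11|f|small": 40,
    "child_2_11|m|small": 35,
    "adolescent_12_17|f|small": 25,
    "adolescent_12_17|m|small": 20,
    "other|f|small": 30,
}


@pytest.fixture(scope="session")
def tiny_market():
    """Small market where panel == population (unit weights)."""
    cfg = MarketConfig(
        seed=11,
        n_stations=3,
        n_days=4,
        n_airings=250,
        n_unique_ads=30,
        population_by_stratum=TINY_POP,
        panel_size_by_stratum=dict(TINY_POP),
    )
    return generate_market(cfg)


@pytest.fixture(scope="session")
def sampled_market():
    """Small market with a genuine panel subsample and non-unit weights."""
    cfg = MarketConfig(
        seed=5,
        n_stations=4,
        n_days=6,
        n_airings=600,
        n_unique_ads=50,
    )
    return generate_market(cfg)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; never share code with the package)
# ---------------------------------------------------------------------------

def brute_force_ledger(airings: pd.DataFrame, ads, viewing: pd.DataFrame):
    """All (member, airing row) hits by explicit double loop."""
    hits = []
    airings = airings.reset_index(drop=True)
    for ai in range(len(airings)):
        st = airings.loc[ai, "station"]
        t = pd.Timestamp(airings.loc[ai, "start"])
        for _, v in viewing.iterrows():
            if (
                v["station"] == st
                and pd.Timestamp(v["start"]) <= t < pd.Timestamp(v["end"])
            ):
                hits.append((v["member_id"], ai))
    return sorted(hits)


def brute_force_group_exposure(airings, ads, viewing, persons):
    """Per-group exposure by explicit person x airing enumeration."""
    totals = {}
    pops = persons.groupby("age_group")["member_id"].count().to_dict()
    v_by_member = {m: g for m, g in zip(persons["member_id"], persons["age_group"])}
    for member, ai in brute_force_ledger(airings, ads, viewing):
        g = v_by_member[member]
        ad = ads[airings.reset_index(drop=True).loc[ai, "ad_id"]]
        totals[g] = totals.get(g, 0.0) + product_weight(ad.n_products)
    return {g: totals.get(g, 0.0) / pops[g] for g in pops}


def brute_force_frequency(airings: pd.DataFrame, ads, catmap):
    """Category weighted frequencies by per-airing accumulation."""
    per_cat: dict[str, int] = {}
    total = 0
    for _, row in airings.iterrows():
        ad = ads[row["ad_id"]]
        unit = min(max(len(ad.products), 1), 3)
        total += unit
        cats = []
        for p in ad.products:
            c = catmap.coarse(p.fine_category)
            if c not in cats:
                cats.append(c)
        for c in cats:
            per_cat[c] = per_cat.get(c, 0) + unit
    return per_cat, total


def make_ad(ad_id, fine_categories, language="en", duration=30, content_key=None):
    """One-liner UniqueAd builder for fixtures."""
    return UniqueAd(
        ad_id=ad_id,
        content_key=content_key or f"ck-{ad_id}",
        language=language,
        duration=duration,
        products=tuple(
            Product(f"{ad_id}-p{i}", f"prod {i}", fc)
            for i, fc in enumerate(fine_categories)
        ),
    )
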