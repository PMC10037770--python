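"""Synthetic advertising market and people-meter panel generator.

Generates stations, unique ads with products, a full-year-style airing
schedule, nutrition tables, technique codings, a synthetic population with
per-stratum viewing behaviour, and a weighted panel subsampled from it.
Ground-truth per-capita exposure is computed by exhaustive enumeration over
the full population, so panel-based estimates can be validated against it.

All randomness flows from ``config.seed`` through named substreams, so each
generation stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .categories import (
    COARSE_CATEGORIES,
    DEFAULT_CATEGORY_MAP,
    _FINE_BY_COARSE,
    CategoryMap,
)
from .coding import TECHNIQUES, AdCoding, resolve_consensus
from .errors import ConfigError
from .exposure import (
    compute_weights,
    per_airing_group_viewers,
    population_by_group,
    split_stratum,
    stratum_label,
)
from .ingest import Product, UniqueAd, product_weight
from .npm import (
    DEFAULT_THRESHOLDS,
    SOURCE_TIERS,
    ThresholdConfig,
    classify_ad,
    classify_products,
)

#: Daily viewing blocks (minutes within a day); sessions never cross blocks,
#: which guarantees one member is never tuned to two stations at once.
BLOCKS: tuple[tuple[int, int], ...] = ((360, 1080), (1080, 1440))


@dataclass(frozen=True)
class ViewingParams:
    """Stratum-level viewing behaviour.

    ``station_prefs`` are unnormalized station weights (None = uniform);
    ``watch_prob`` is the per-block probability of a session (None derives
    it from mean daily minutes).
    """

    mean_daily_minutes: float
    station_prefs: Optional[tuple[float, ...]] = None
    watch_prob: Optional[float] = None


_DEFAULT_POPULATION: dict[str, int] = {
    "child_2_11|f|small": 600,
    "child_2_11|f|large": 600,
    "child_2_11|m|small": 700,
    "child_2_11|m|large": 600,
    "adolescent_12_17|f|small": 400,
    "adolescent_12_17|f|large": 400,
    "adolescent_12_17|m|small": 350,
    "adolescent_12_17|m|large": 350,
    "other|f|small": 1500,
    "other|f|large": 1500,
    "other|m|small": 1500,
    "other|m|large": 1500,
}

_DEFAULT_PANEL: dict[str, int] = {
    "child_2_11|f|small": 44,
    "child_2_11|f|large": 44,
    "child_2_11|m|small": 44,
    "child_2_11|m|large": 43,
    "adolescent_12_17|f|small": 27,
    "adolescent_12_17|f|large": 27,
    "adolescent_12_17|m|small": 26,
    "adolescent_12_17|m|large": 26,
    "other|f|small": 5,
    "other|f|large": 5,
    "other|m|small": 5,
    "other|m|large": 5,
}

_DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "restaurants": 0.49,
    "snacks": 0.09,
    "candy_and_chocolate": 0.09,
    "dairy": 0.08,
    "breakfast_food": 0.06,
    "beverages": 0.05,
    "miscellaneous": 0.035,
    "sweet_baked_goods_desserts": 0.04,
    "entrees": 0.03,
    "fruits_vegetables": 0.02,
    "bread": 0.005,
    "condiments": 0.005,
    "water": 0.005,
}
# make the mix sum exactly to 1
_DEFAULT_CATEGORY_MIX["restaurants"] += 1.0 - sum(_DEFAULT_CATEGORY_MIX.values())

_DEFAULT_VIEWING: dict[str, ViewingParams] = {
    "child_2_11": ViewingParams(mean_daily_minutes=150.0),
    "adolescent_12_17": ViewingParams(mean_daily_minutes=100.0),
    "other": ViewingParams(mean_daily_minutes=120.0),
}


@dataclass(frozen=True)
class MarketConfig:
    """Parameters of the synthetic market."""

    n_stations: int = 4
    n_days: int = 30
    n_airings: int = 5000
    n_unique_ads: int = 200
    population_by_stratum: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_POPULATION)
    )
    panel_size_by_stratum: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_PANEL)
    )
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_CATEGORY_MIX)
    )
    products_per_ad_dist: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.05, 1: 0.55, 2: 0.20, 3: 0.12, 4: 0.08}
    )
    p_exceeds_threshold: float = 0.85
    nutrition_missing_rate: float = 0.15
    p_cross_category_product: float = 0.15
    viewing_model_params: Mapping[str, ViewingParams] = field(
        default_factory=lambda: dict(_DEFAULT_VIEWING)
    )
    thresholds: ThresholdConfig = DEFAULT_THRESHOLDS
    start_date: str = "2019-01-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_stations < 1:
            raise ConfigError("n_stations must be >= 1")
        if self.n_days < 1:
            raise ConfigError("n_days must be >= 1")
        if self.n_airings < 0:
            raise ConfigError("n_airings must be >= 0")
        if self.n_unique_ads < 1:
            raise ConfigError("n_unique_ads must be >= 1")
        if abs(sum(self.category_mix.values()) - 1.0) > 1e-6:
            raise ConfigError("category_mix proportions must sum to 1")
        bad = set(self.category_mix) - set(COARSE_CATEGORIES)
        if bad:
            raise ConfigError(f"category_mix has unknown categories: {sorted(bad)}")
        if abs(sum(self.products_per_ad_dist.values()) - 1.0) > 1e-6:
            raise ConfigError("products_per_ad_dist must sum to 1")
        if any(k < 0 for k in self.products_per_ad_dist):
            raise ConfigError("products_per_ad_dist keys must be >= 0")
        if not 0.0 <= self.p_exceeds_threshold <= 1.0:
            raise ConfigError("p_exceeds_threshold must be in [0, 1]")
        if not 0.0 <= self.nutrition_missing_rate <= 1.0:
            raise ConfigError("nutrition_missing_rate must be in [0, 1]")
        for s, n in self.panel_size_by_stratum.items():
            if s not in self.population_by_stratum:
                raise ConfigError(f"panel_size_by_stratum: unknown stratum {s!r}")
            if n > self.population_by_stratum[s]:
                raise ConfigError(
                    f"panel_size_by_stratum[{s!r}] exceeds population"
                )
        for s in self.population_by_stratum:
            split_stratum(s)  # raises with the offending label
            age = s.split("|")[0]
            if age not in self.viewing_model_params:
                raise ConfigError(f"viewing_model_params missing age group {age!r}")
        for age, vp in self.viewing_model_params.items():
            if vp.mean_daily_minutes <= 0:
                raise ConfigError(
                    f"viewing_model_params[{age!r}].mean_daily_minutes must be > 0"
                )
            if vp.station_prefs is not None and len(vp.station_prefs) != self.n_stations:
                raise ConfigError(
                    f"viewing_model_params[{age!r}].station_prefs length "
                    f"!= n_stations"
                )


@dataclass(frozen=True)
class GroundTruth:
    """Exhaustive-enumeration exposure over the full synthetic population.

    ``by_group`` maps age group to ads/person/period; ``by_group_slice``
    nests group -> dimension -> value -> ads/person/period.
    """

    by_group: Mapping[str, float]
    by_group_slice: Mapping[str, Mapping[str, Mapping[str, float]]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"by_group": dict(self.by_group),
                 "by_group_slice": {g: {d: dict(v) for d, v in dims.items()}
                                    for g, dims in self.by_group_slice.items()}},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        data = json.loads(Path(path).read_text())
        return cls(by_group=data["by_group"], by_group_slice=data["by_group_slice"])


def compute_ground_truth(
    airings: pd.DataFrame,
    ads: Mapping[str, UniqueAd],
    viewing: pd.DataFrame,
    persons: pd.DataFrame,
    *,
    catmap: Optional[CategoryMap] = None,
    ad_labels: Optional[Mapping[str, str]] = None,
) -> GroundTruth:
    """Exact exposure per group by enumerating every person x airing pair.

    ``viewing`` must cover the whole synthetic population (``persons``:
    member_id, age_group, optional weight defaulting to 1). Exposure(group)
    sums, over airings, the tuned-in persons times the ad's capped product
    weight, divided by the group population. Station and category slices are
    always computed; technique and healthfulness slices when available.
    """
    persons = persons.copy()
    if "weight" not in persons.columns:
        persons["weight"] = 1.0
    pop = persons.groupby("age_group")["weight"].sum()
    airings = airings.reset_index(drop=True)
    viewers = per_airing_group_viewers(airings, viewing, persons)

    pw = np.array(
        [product_weight(ads[a].n_products) for a in airings["ad_id"]], dtype=float
    ) if len(airings) else np.zeros(0)
    groups = sorted(pop.index)

    by_group: dict[str, float] = {}
    by_slice: dict[str, dict[str, dict[str, float]]] = {g: {} for g in groups}
    a_station = airings["station"].to_numpy() if len(airings) else np.array([])
    ad_ids = airings["ad_id"].to_numpy() if len(airings) else np.array([])

    catmap = catmap or DEFAULT_CATEGORY_MAP
    cats_of = {a: ads[a].coarse_categories(catmap) for a in ads}
    techs_present = any(ads[a].techniques for a in ads)

    for g in groups:
        v = viewers.get(g, np.zeros(len(airings)))
        w = v * pw
        by_group[g] = float(w.sum() / pop[g])
        st: dict[str, float] = {}
        for s in np.unique(a_station):
            st[str(s)] = float(w[a_station == s].sum() / pop[g])
        by_slice[g]["station"] = st
        cat: dict[str, float] = {}
        for c in COARSE_CATEGORIES:
            touching = {a for a, cs in cats_of.items() if c in cs}
            if not touching:
                continue
            mask = np.isin(ad_ids, sorted(touching))
            if mask.any():
                cat[c] = float(w[mask].sum() / pop[g])
        by_slice[g]["category"] = cat
        if techs_present:
            te: dict[str, float] = {}
            for t in TECHNIQUES:
                having = {a for a in ads if (ads[a].techniques or {}).get(t)}
                if not having:
                    continue
                mask = np.isin(ad_ids, sorted(having))
                if mask.any():
                    te[t] = float(w[mask].sum() / pop[g])
            by_slice[g]["technique"] = te
        if ad_labels is not None:
            npm: dict[str, float] = {}
            for label in ("healthy", "unhealthy"):
                tagged = {a for a, l in ad_labels.items() if l == label}
                if not tagged:
                    continue
                mask = np.isin(ad_ids, sorted(tagged))
                if mask.any():
                    npm[label] = float(w[mask].sum() / pop[g])
            by_slice[g]["npm"] = npm
    return GroundTruth(by_group=by_group, by_group_slice=by_slice)


# ---------------------------------------------------------------------------
# Generation stages
# ---------------------------------------------------------------------------

def _generate_unique_ads(config: MarketConfig) -> tuple[dict[str, UniqueAd], dict[str, str]]:
    """Create the unique-ad pool; returns (ads, mix category per ad)."""
    rng = substream(config.seed, "ads")
    cats = list(config.category_mix)
    probs = np.array([config.category_mix[c] for c in cats], dtype=float)
    ad_cats = rng.choice(len(cats), size=config.n_unique_ads, p=probs)
    counts = list(config.products_per_ad_dist)
    cprobs = np.array([config.products_per_ad_dist[k] for k in counts], dtype=float)
    n_products = rng.choice(counts, size=config.n_unique_ads, p=cprobs)

    ads: dict[str, UniqueAd] = {}
    mix_cat: dict[str, str] = {}
    pid = 0
    for i in range(config.n_unique_ads):
        coarse = cats[int(ad_cats[i])]
        products = []
        for j in range(int(n_products[i])):
            c = coarse
            if j > 0 and rng.random() < config.p_cross_category_product:
                c = cats[int(rng.integers(len(cats)))]
            fines = _FINE_BY_COARSE[c]
            fine = fines[int(rng.integers(len(fines)))]
            products.append(
                Product(product_id=f"P{pid:05d}", name=f"{fine} {pid}", fine_category=fine)
            )
            pid += 1
        ad_id = f"AD{i:04d}"
        ads[ad_id] = UniqueAd(
            ad_id=ad_id,
            content_key=f"ck{i:05d}",
            language="fr" if rng.random() < 0.1 else "en",
            duration=15 if rng.random() < 0.5 else 30,
            products=tuple(products),
        )
        mix_cat[ad_id] = coarse
    return ads, mix_cat


def _generate_nutrition(config: MarketConfig, ads: Mapping[str, UniqueAd]) -> pd.DataFrame:
    rng = substream(config.seed, "nutrition")
    limits = config.thresholds.thresholds
    nutrients = list(limits)
    rows = []
    restaurant_fines = set(_FINE_BY_COARSE["restaurants"])
    for ad in ads.values():
        for p in ad.products:
            missing = rng.random() < config.nutrition_missing_rate
            if p.fine_category in restaurant_fines:
                tier = "menu_flip_2016" if rng.random() < 0.8 else "company_ca_site"
            else:
                tier = "flip_2017" if rng.random() < 0.8 else SOURCE_TIERS[
                    2 + int(rng.integers(4))
                ]
            row = {
                "product_id": p.product_id,
                "name": p.name,
                "fine_category": p.fine_category,
                "basis": config.thresholds.basis,
                "source_tier": tier,
                "missing": missing,
            }
            amounts = {
                n: float(limits[n] * 0.9 * rng.random()) for n in nutrients
            }
            flags = {f: bool(rng.random() < 0.5) for f in ("fat", "sugar", "sodium")}
            if not missing and rng.random() < config.p_exceeds_threshold:
                n = nutrients[int(rng.integers(len(nutrients)))]
                amounts[n] = float(limits[n] * rng.uniform(1.1, 2.5))
                from .npm import ADDED_FLAG_FOR

                flags[ADDED_FLAG_FOR[n]] = True
            if missing:
                for n in nutrients:
                    row[n] = np.nan
            else:
                row.update({n: round(a, 2) for n, a in amounts.items()})
            row.update({f"added_{f}": v for f, v in flags.items()})
            rows.append(row)
    cols = [
        "product_id", "name", "fine_category", "basis",
        *nutrients, "added_fat", "added_sugar", "added_sodium",
        "source_tier", "missing",
    ]
    return pd.DataFrame(rows, columns=cols)


def _generate_airings(
    config: MarketConfig, ads: Mapping[str, UniqueAd], mix_cat: Mapping[str, str],
    stations: Sequence[str],
) -> pd.DataFrame:
    rng = substream(config.seed, "airings")
    if config.n_airings == 0:
        return pd.DataFrame(columns=["station", "start", "ad_id"])
    # airing probability of an ad: its category share split among the pool ads
    # assigned to that category
    ad_ids = sorted(ads)
    cat_counts: dict[str, int] = {}
    for a in ad_ids:
        cat_counts[mix_cat[a]] = cat_counts.get(mix_cat[a], 0) + 1
    w = np.array(
        [config.category_mix[mix_cat[a]] / cat_counts[mix_cat[a]] for a in ad_ids]
    )
    w = w / w.sum()
    chosen = rng.choice(len(ad_ids), size=config.n_airings, p=w)
    station_pop = rng.dirichlet(np.full(len(stations), 5.0))
    st = rng.choice(len(stations), size=config.n_airings, p=station_pop)
    minutes = rng.integers(0, config.n_days * 1440, size=config.n_airings)
    base = np.datetime64(config.start_date)
    start = base + minutes.astype("timedelta64[m]")
    df = pd.DataFrame(
        {
            "station": [stations[i] for i in st],
            "start": pd.to_datetime(start),
            "ad_id": [ad_ids[i] for i in chosen],
        }
    )
    return df.sort_values(["start", "station"], kind="stable").reset_index(drop=True)


def _generate_persons(config: MarketConfig) -> pd.DataFrame:
    rows = []
    i = 0
    for label in sorted(config.population_by_stratum):
        age, sex, hh = split_stratum(label)
        n = int(config.population_by_stratum[label])
        for _ in range(n):
            rows.append((f"M{i:06d}", age, sex, hh, label))
            i += 1
    return pd.DataFrame(
        rows, columns=["member_id", "age_group", "sex", "hh_band", "stratum"]
    )


def _generate_viewing(
    config: MarketConfig, persons: pd.DataFrame, stations: Sequence[str]
) -> pd.DataFrame:
    rng = substream(config.seed, "viewing")
    base = np.datetime64(config.start_date)
    frames = []
    for age, sub in persons.groupby("age_group", sort=True):
        vp = config.viewing_model_params[age]
        prefs = (
            np.asarray(vp.station_prefs, dtype=float)
            if vp.station_prefs is not None
            else np.ones(len(stations))
        )
        prefs = prefs / prefs.sum()
        q = (
            vp.watch_prob
            if vp.watch_prob is not None
            else min(0.9, vp.mean_daily_minutes / 240.0)
        )
        n_p = len(sub)
        member = np.repeat(sub["member_id"].to_numpy(), config.n_days)
        day = np.tile(np.arange(config.n_days), n_p)
        for b0, b1 in BLOCKS:
            length = b1 - b0
            watch = rng.random(n_p * config.n_days) < q
            k = int(watch.sum())
            if not k:
                continue
            dur = np.ceil(rng.exponential(vp.mean_daily_minutes / 2.0, k))
            dur = np.clip(dur, 1, length - 1).astype(np.int64)
            start_min = b0 + np.floor(
                rng.random(k) * (length - dur)
            ).astype(np.int64)
            st_idx = rng.choice(len(stations), size=k, p=prefs)
            abs_start = day[watch] * 1440 + start_min
            frames.append(
                pd.DataFrame(
                    {
                        "member_id": member[watch],
                        "station": np.asarray(stations)[st_idx],
                        "start": pd.to_datetime(
                            base + abs_start.astype("timedelta64[m]")
                        ),
                        "end": pd.to_datetime(
                            base + (abs_start + dur).astype("timedelta64[m]")
                        ),
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["member_id", "station", "start", "end"])
    return pd.concat(frames, ignore_index=True)


def _generate_codings(
    config: MarketConfig, ads: Mapping[str, UniqueAd]
) -> tuple[dict[str, dict[str, dict[str, bool]]], dict[str, UniqueAd]]:
    """Simulate three coders and attach consensus technique vectors to ads."""
    rng = substream(config.seed, "coding")
    prevalence = rng.uniform(0.05, 0.40, size=len(TECHNIQUES))
    coders = ("coder_1", "coder_2", "coder_3")
    codings: dict[str, dict[str, dict[str, bool]]] = {c: {} for c in coders}
    coded_ads: dict[str, UniqueAd] = {}
    for ad_id in sorted(ads):
        truth = rng.random(len(TECHNIQUES)) < prevalence
        per_coder = []
        for c in coders:
            flips = rng.random(len(TECHNIQUES)) < 0.03
            vec = np.logical_xor(truth, flips)
            pres = {t: bool(v) for t, v in zip(TECHNIQUES, vec)}
            codings[c][ad_id] = pres
            per_coder.append(AdCoding(ad_id=ad_id, presence=pres, coder_id=c))
        consensus = resolve_consensus(per_coder)
        presence = {t: bool(v) for t, v in consensus.presence.items()}
        coded_ads[ad_id] = replace(ads[ad_id], techniques=presence)
    return codings, coded_ads


# ---------------------------------------------------------------------------
# Top-level generation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticMarket:
    """Everything one market generation run produces."""

    config: MarketConfig
    stations: list[str]
    airings: pd.DataFrame
    ads: dict[str, UniqueAd]
    products: pd.DataFrame
    persons: pd.DataFrame          # full synthetic population
    population_viewing: pd.DataFrame
    panel: pd.DataFrame            # weighted panel roster
    viewing: pd.DataFrame          # panel members' viewing only
    population_by_stratum: dict[str, int]
    ad_labels: dict[str, str]
    codings: dict[str, dict[str, dict[str, bool]]]
    truth: GroundTruth
    catmap: CategoryMap

    @property
    def population_by_group(self) -> dict[str, int]:
        return population_by_group(self.population_by_stratum)

    def save(self, out_dir: str | Path) -> None:
        from .exposure import write_viewing_csv
        from .ingest import ads_to_json, write_airings_csv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_airings_csv(self.airings, out / "airings.csv")
        ads_to_json(self.ads.values(), out / "ads.json")
        self.products.to_csv(out / "products.csv", index=False)
        self.panel.to_csv(out / "panel.csv", index=False)
        write_viewing_csv(self.viewing, out / "viewing.csv")
        (out / "population.json").write_text(
            json.dumps(self.population_by_stratum, indent=1)
        )
        self.truth.to_json(out / "truth.json")
        self.catmap.to_csv(out / "category_map.csv")
        coding_rows = []
        for coder, by_ad in self.codings.items():
            for ad_id, pres in by_ad.items():
                coding_rows.append(
                    {"ad_id": ad_id, "coder_id": coder,
                     **{t: int(pres[t]) for t in TECHNIQUES}}
                )
        pd.DataFrame(coding_rows).to_csv(out / "codings.csv", index=False)
        (out / "ad_labels.json").write_text(json.dumps(self.ad_labels, indent=1))


def generate_market(config: MarketConfig) -> SyntheticMarket:
    """Generate a complete synthetic market; deterministic given the seed."""
    config.validate()
    stations = [f"ST{i:02d}" for i in range(config.n_stations)]
    ads, mix_cat = _generate_unique_ads(config)
    products = _generate_nutrition(config, ads)
    airings = _generate_airings(config, ads, mix_cat, stations)
    persons = _generate_persons(config)
    pop_viewing = _generate_viewing(config, persons, stations)

    # classified healthfulness of every ad
    labels = classify_products(products, config.thresholds)
    codings, ads = _generate_codings(config, ads)
    ad_labels = {a: classify_ad(ads[a], labels) for a in ads}

    # weighted panel subsampled from the population, stratum by stratum
    rng = substream(config.seed, "panel")
    chosen = []
    for label in sorted(config.panel_size_by_stratum):
        n = int(config.panel_size_by_stratum[label])
        members = persons.loc[persons["stratum"] == label, "member_id"].to_numpy()
        if n > 0:
            chosen.append(rng.choice(members, size=n, replace=False))
    panel_ids = np.concatenate(chosen) if chosen else np.array([], dtype=object)
    panel = persons[persons["member_id"].isin(panel_ids)].reset_index(drop=True)
    panel = compute_weights(
        panel[["member_id", "age_group", "sex", "hh_band"]],
        dict(config.population_by_stratum),
    )
    viewing = pop_viewing[pop_viewing["member_id"].isin(panel["member_id"])]
    viewing = viewing.reset_index(drop=True)

    truth = compute_ground_truth(
        airings, ads, pop_viewing, persons[["member_id", "age_group"]],
        catmap=DEFAULT_CATEGORY_MAP, ad_labels=ad_labels,
    )
    return SyntheticMarket(
        config=config,
        stations=stations,
        airings=airings,
        ads=ads,
        products=products,
        persons=persons,
        population_viewing=pop_viewing,
        panel=panel,
        viewing=viewing,
        population_by_stratum=dict(config.population_by_stratum),
        ad_labels=ad_labels,
        codings=codings,
        truth=truth,
        catmap=DEFAULT_CATEGORY_MAP,
    )


# ---------------------------------------------------------------------------
# Config file support
# ---------------------------------------------------------------------------

def load_market_config(path: str | Path) -> MarketConfig:
    """Load a MarketConfig from YAML or JSON."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if "viewing_model_params" in data:
        data["viewing_model_params"] = {
            age: ViewingParams(
                mean_daily_minutes=float(v["mean_daily_minutes"]),
                station_prefs=tuple(v["station_prefs"]) if v.get("station_prefs") else None,
                watch_prob=v.get("watch_prob"),
            )
            for age, v in data["viewing_model_params"].items()
        }
    if "products_per_ad_dist" in data:
        data["products_per_ad_dist"] = {
            int(k): float(v) for k, v in data["products_per_ad_dist"].items()
        }
    if "thresholds" in data:
        t = data["thresholds"]
        data["thresholds"] = ThresholdConfig(
            thresholds={str(k): float(v) for k, v in t["thresholds"].items()},
            basis=t.get("basis", "per_serving"),
        )
    cfg = MarketConfig(**data)
    cfg.validate()
    return cfg
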