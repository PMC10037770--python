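"""End-to-end assembly: raw market data in, report tables out."""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd

from .categories import CategoryMap
from .coding import TECHNIQUES
from .exposure import (
    ADOLESCENT,
    CHILD,
    count_impressions,
    estimate_exposure,
    exposure_by_group,
    population_by_group,
)
from .ingest import UniqueAd, frequency_table, product_weight, weighted_frequency
from .report import (
    ReportConfig,
    category_table,
    healthfulness_table,
    station_table,
    technique_table,
)


def frequency_by_station(
    airings: pd.DataFrame, ads: Mapping[str, UniqueAd]
) -> dict[str, float]:
    """Weighted frequency per station (partition of the grand total)."""
    pw = airings["ad_id"].map(lambda a: product_weight(ads[a].n_products))
    return (
        pd.DataFrame({"station": airings["station"], "w": pw})
        .groupby("station")["w"].sum().astype(float).to_dict()
    )


def frequency_by_technique(
    airings: pd.DataFrame, ads: Mapping[str, UniqueAd]
) -> dict[str, float]:
    counts = airings["ad_id"].value_counts()
    out: dict[str, float] = {}
    for ad_id, n in counts.items():
        ad = ads[ad_id]
        wf = weighted_frequency(ad.n_products, int(n))
        for t, present in (ad.techniques or {}).items():
            if present:
                out[t] = out.get(t, 0.0) + wf
    return out


def frequency_by_label(
    airings: pd.DataFrame,
    ads: Mapping[str, UniqueAd],
    ad_labels: Mapping[str, str],
) -> dict[str, float]:
    counts = airings["ad_id"].value_counts()
    out: dict[str, float] = {}
    for ad_id, n in counts.items():
        label = ad_labels.get(ad_id, "unclassified")
        wf = weighted_frequency(ads[ad_id].n_products, int(n))
        out[label] = out.get(label, 0.0) + wf
    return out


def run_analysis(
    airings: pd.DataFrame,
    ads: Mapping[str, UniqueAd],
    viewing: pd.DataFrame,
    panel: pd.DataFrame,
    population_by_stratum: Mapping[str, int],
    catmap: CategoryMap,
    ad_labels: Optional[Mapping[str, str]] = None,
    config: ReportConfig = ReportConfig(),
) -> dict[str, pd.DataFrame]:
    """Run the full estimation pipeline and assemble tables 2-5.

    Returns a dict with keys ``station``, ``category``, ``technique`` and
    (when ad labels are available) ``healthfulness``.
    """
    ledger = count_impressions(airings, ads, viewing)
    pbg = {
        g: p
        for g, p in population_by_group(population_by_stratum).items()
        if g in (CHILD, ADOLESCENT)
    }

    est_total = estimate_exposure(ledger, panel, pbg, "total")
    totals = exposure_by_group(est_total)
    total_pair = (
        totals.get(CHILD, {}).get("total", 0.0),
        totals.get(ADOLESCENT, {}).get("total", 0.0),
    )

    tables: dict[str, pd.DataFrame] = {}
    est_station = estimate_exposure(ledger, panel, pbg, "station")
    tables["station"] = station_table(
        est_station, frequency_by_station(airings, ads), config
    )
    cat_freq = frequency_table(airings, ads, catmap)
    est_cat = estimate_exposure(ledger, panel, pbg, "category", ads=ads, catmap=catmap)
    tables["category"] = category_table(est_cat, cat_freq, total_pair, config)

    if any(ads[a].techniques for a in ads):
        est_tech = estimate_exposure(ledger, panel, pbg, "technique", ads=ads)
        tables["technique"] = technique_table(
            est_tech,
            frequency_by_technique(airings, ads),
            float(cat_freq.attrs["total"]),
            config,
        )
    if ad_labels is not None:
        est_npm = estimate_exposure(
            ledger, panel, pbg, "npm", ads=ads, ad_labels=ad_labels
        )
        tables["healthfulness"] = healthfulness_table(
            est_npm, frequency_by_label(airings, ads, ad_labels), config
        )
    return tables
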