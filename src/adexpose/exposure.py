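"""Post-stratification weighting, impressions, GRPs and per-capita exposure.

A panel member yields an impression for an airing when one of their viewing
intervals on the airing's station covers the airing's start instant
(half-open [start, end) convention; no partial-exposure prorating).
Impressions are product-weighted (capped at 3) so exposure tables count
advertised food products. Gross rating points divide weighted impressions
by the market population times 100; exposure in ads/person/period is
GRP / 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryMap
from .errors import ExposureError, ValidationError
from .ingest import UniqueAd, product_weight

CHILD = "child_2_11"
ADOLESCENT = "adolescent_12_17"
OTHER = "other"

AGE_GROUPS = (CHILD, ADOLESCENT, OTHER)


def stratum_label(age_group: str, sex: str, hh_band: str) -> str:
    return f"{age_group}|{sex}|{hh_band}"


def split_stratum(label: str) -> tuple[str, str, str]:
    parts = label.split("|")
    if len(parts) != 3:
        raise ValidationError(f"stratum label {label!r} is not age|sex|hh_band")
    return parts[0], parts[1], parts[2]


@dataclass(frozen=True)
class ExposureEstimate:
    """Per-capita exposure for one population group and one slice."""

    group: str
    slice: tuple[str, str]  # (dimension, value), e.g. ("station", "ST01")
    impressions: float
    population: float
    grp: float
    exposure: float

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ExposureError(f"population must be positive for {self.group}")


def _make_estimate(group: str, sl: tuple[str, str], impressions: float,
                   population: float) -> ExposureEstimate:
    grp = impressions / population * 100.0
    return ExposureEstimate(
        group=group, slice=sl, impressions=impressions, population=population,
        grp=grp, exposure=grp / 100.0,
    )


# ---------------------------------------------------------------------------
# Weighting
# ---------------------------------------------------------------------------

def compute_weights(
    panel: pd.DataFrame, population_by_stratum: Mapping[str, int]
) -> pd.DataFrame:
    """Fill post-stratification weights: population cell / panel cell.

    ``panel`` needs columns member_id, age_group, sex, hh_band. Weights in a
    stratum sum to that stratum's population. A stratum with population but
    no panelists is an error listing the stratum.
    """
    out = panel.copy()
    strata = out.apply(
        lambda r: stratum_label(r["age_group"], r["sex"], r["hh_band"]), axis=1
    )
    counts = strata.value_counts()
    empty = [
        s for s, pop in population_by_stratum.items()
        if pop > 0 and counts.get(s, 0) == 0
    ]
    if empty:
        raise ExposureError(f"strata with population but no panelists: {sorted(empty)}")
    unknown = [s for s in counts.index if s not in population_by_stratum]
    if unknown:
        raise ExposureError(f"panel strata missing from population: {sorted(unknown)}")
    out["weight"] = strata.map(
        lambda s: population_by_stratum[s] / counts[s]
    ).astype(float)
    return out


def population_by_group(population_by_stratum: Mapping[str, int]) -> dict[str, int]:
    """Aggregate stratum populations to age-group totals."""
    out: dict[str, int] = {}
    for label, pop in population_by_stratum.items():
        age, _, _ = split_stratum(label)
        out[age] = out.get(age, 0) + int(pop)
    return out


# ---------------------------------------------------------------------------
# Impressions
# ---------------------------------------------------------------------------

def validate_viewing(viewing: pd.DataFrame) -> None:
    """Check interval sanity: end > start; no cross-station overlap per member."""
    start = pd.to_datetime(viewing["start"])
    end = pd.to_datetime(viewing["end"])
    if (end <= start).any():
        bad = int((end <= start).sum())
        raise ValidationError(f"{bad} viewing intervals have end <= start")
    df = viewing.assign(_s=start, _e=end).sort_values(["member_id", "_s"], kind="stable")
    same_member = df["member_id"].to_numpy()[1:] == df["member_id"].to_numpy()[:-1]
    overlap = df["_s"].to_numpy()[1:] < df["_e"].to_numpy()[:-1]
    diff_station = df["station"].to_numpy()[1:] != df["station"].to_numpy()[:-1]
    if (same_member & overlap & diff_station).any():
        raise ValidationError(
            "overlapping viewing intervals on different stations for one member"
        )


def _as_ns(x: pd.Series) -> np.ndarray:
    return pd.to_datetime(x).to_numpy().astype("datetime64[ns]").astype(np.int64)


def count_impressions(
    airings: pd.DataFrame,
    ads: Mapping[str, UniqueAd],
    viewing: pd.DataFrame,
) -> pd.DataFrame:
    """Build the impression ledger: one row per (member, airing) hit.

    Columns: member_id, airing_idx, station, ad_id, product_weight. A member
    hits an airing iff they have a viewing interval on the airing's station
    with start <= airing.start < end.
    """
    airings = airings.reset_index(drop=True)
    unknown = set(airings["ad_id"]) - set(ads)
    if unknown:
        raise ExposureError(f"airings reference unknown ads: {sorted(unknown)[:5]}")
    validate_viewing(viewing)
    if not len(viewing) or not len(airings):
        return pd.DataFrame(
            columns=["member_id", "airing_idx", "station", "ad_id", "product_weight"]
        )

    a_station = airings["station"].to_numpy()
    a_time = _as_ns(airings["start"])
    pw = airings["ad_id"].map(lambda a: product_weight(ads[a].n_products)).to_numpy()

    v_station = viewing["station"].to_numpy()
    v_start = _as_ns(viewing["start"])
    v_end = _as_ns(viewing["end"])
    v_member = viewing["member_id"].to_numpy()

    members, airing_rows = [], []
    for s in np.unique(a_station):
        sel = a_station == s
        rows = np.flatnonzero(sel)
        order = np.argsort(a_time[sel], kind="stable")
        times, rows = a_time[sel][order], rows[order]
        vm = np.flatnonzero(v_station == s)
        if not len(vm):
            continue
        lo = np.searchsorted(times, v_start[vm], side="left")
        hi = np.searchsorted(times, v_end[vm], side="left")
        counts = hi - lo
        keep = counts > 0
        lo, counts, vm = lo[keep], counts[keep], vm[keep]
        total = int(counts.sum())
        if not total:
            continue
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        pos = np.repeat(lo, counts) + offs
        members.append(np.repeat(v_member[vm], counts))
        airing_rows.append(rows[pos])

    if not members:
        return pd.DataFrame(
            columns=["member_id", "airing_idx", "station", "ad_id", "product_weight"]
        )
    member_id = np.concatenate(members)
    airing_idx = np.concatenate(airing_rows)
    return pd.DataFrame(
        {
            "member_id": member_id,
            "airing_idx": airing_idx,
            "station": a_station[airing_idx],
            "ad_id": airings["ad_id"].to_numpy()[airing_idx],
            "product_weight": pw[airing_idx],
        }
    )


def per_airing_group_viewers(
    airings: pd.DataFrame, viewing: pd.DataFrame, persons: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Weighted tuned-in persons per airing, by age group.

    ``persons`` needs member_id, age_group, weight. Returns, for each age
    group, an array aligned with ``airings`` rows holding the sum of member
    weights whose viewing covers that airing's start. Linear-time sweep per
    station; used for exhaustive ground-truth computation over full
    synthetic populations.
    """
    airings = airings.reset_index(drop=True)
    n = len(airings)
    groups = sorted(persons["age_group"].unique())
    out = {g: np.zeros(n) for g in groups}
    if not n or not len(viewing):
        return out
    validate_viewing(viewing)

    a_station = airings["station"].to_numpy()
    a_time = _as_ns(airings["start"])
    idx = persons.set_index("member_id")
    v_group = idx["age_group"].reindex(viewing["member_id"]).to_numpy()
    v_w = idx["weight"].reindex(viewing["member_id"]).to_numpy(dtype=float)
    v_station = viewing["station"].to_numpy()
    v_start = _as_ns(viewing["start"])
    v_end = _as_ns(viewing["end"])

    for s in np.unique(a_station):
        sel = a_station == s
        rows = np.flatnonzero(sel)
        order = np.argsort(a_time[sel], kind="stable")
        times, rows = a_time[sel][order], rows[order]
        vm = v_station == s
        if not vm.any():
            continue
        lo = np.searchsorted(times, v_start[vm], side="left")
        hi = np.searchsorted(times, v_end[vm], side="left")
        gv, wv = v_group[vm], v_w[vm]
        for g in groups:
            gm = gv == g
            if not gm.any():
                continue
            diff = np.zeros(len(times) + 1)
            np.add.at(diff, lo[gm], wv[gm])
            np.add.at(diff, hi[gm], -wv[gm])
            out[g][rows] += np.cumsum(diff[:-1])
    return out


# ---------------------------------------------------------------------------
# Exposure estimation
# ---------------------------------------------------------------------------

def _slice_frame(
    slice_by: str,
    ad_ids: Sequence[str],
    ads: Optional[Mapping[str, UniqueAd]],
    catmap: Optional[CategoryMap],
    ad_labels: Optional[Mapping[str, str]],
) -> pd.DataFrame:
    """Map each ad id to its slice values (one row per (ad, value))."""
    rows: list[tuple[str, str]] = []
    if slice_by == "category":
        if ads is None or catmap is None:
            raise ValidationError("category slicing needs ads and a category map")
        for a in ad_ids:
            for cat in ads[a].coarse_categories(catmap):
                rows.append((a, cat))
    elif slice_by == "technique":
        if ads is None:
            raise ValidationError("technique slicing needs ads")
        for a in ad_ids:
            techs = ads[a].techniques or {}
            for t, present in techs.items():
                if present:
                    rows.append((a, t))
    elif slice_by == "npm":
        if ad_labels is None:
            raise ValidationError("npm slicing needs ad labels")
        for a in ad_ids:
            label = ad_labels.get(a, "unclassified")
            if label != "unclassified":
                rows.append((a, label))
    else:
        raise ValidationError(f"unknown slice dimension {slice_by!r}")
    return pd.DataFrame(rows, columns=["ad_id", "slice_value"])


def estimate_exposure(
    ledger: pd.DataFrame,
    panel: pd.DataFrame,
    population_by_group: Mapping[str, float],
    slice_by: str = "total",
    *,
    ads: Optional[Mapping[str, UniqueAd]] = None,
    catmap: Optional[CategoryMap] = None,
    ad_labels: Optional[Mapping[str, str]] = None,
) -> list[ExposureEstimate]:
    """Turn the impression ledger into GRP/exposure estimates per group.

    ``slice_by`` is one of total, station, category, technique, npm. The
    total and station slices count every ledger row once; category and
    technique slices give each row its full weight in every slice value the
    ad touches (so category slices are super-additive in the presence of
    multi-category ads, matching the frequency-table convention).
    """
    for g, pop in population_by_group.items():
        if pop <= 0:
            raise ExposureError(f"zero or negative population for group {g!r}")

    df = ledger.merge(
        panel[["member_id", "age_group", "weight"]], on="member_id", how="left"
    )
    if df["weight"].isna().any():
        raise ExposureError("ledger references members missing from the panel")
    df = df[df["age_group"].isin(population_by_group)]
    df = df.assign(_w=df["product_weight"] * df["weight"])

    if slice_by == "total":
        df = df.assign(slice_value="total")
    elif slice_by == "station":
        df = df.assign(slice_value=df["station"])
    else:
        sl = _slice_frame(slice_by, sorted(set(df["ad_id"])), ads, catmap, ad_labels)
        df = df.merge(sl, on="ad_id", how="inner")

    sums = df.groupby(["age_group", "slice_value"], sort=True)["_w"].sum()
    estimates: list[ExposureEstimate] = []
    values = sorted(sums.index.get_level_values("slice_value").unique())
    if slice_by == "total" and not values:
        values = ["total"]
    for g in sorted(population_by_group):
        pop = float(population_by_group[g])
        for v in values:
            imp = float(sums.get((g, v), 0.0))
            estimates.append(_make_estimate(g, (slice_by, v), imp, pop))
    return estimates


def exposure_by_group(
    estimates: Sequence[ExposureEstimate],
) -> dict[str, dict[str, float]]:
    """Reshape estimates to {group: {slice value: exposure}}."""
    out: dict[str, dict[str, float]] = {}
    for e in estimates:
        out.setdefault(e.group, {})[e.slice[1]] = e.exposure
    return out


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def read_panel_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"member_id": str})
    needed = {"member_id", "age_group", "sex", "hh_band"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"panel roster missing columns: {sorted(missing)}")
    return df


def read_viewing_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"member_id": str, "station": str})
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def write_viewing_csv(viewing: pd.DataFrame, path: str | Path) -> None:
    out = viewing.copy()
    out["start"] = pd.to_datetime(out["start"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["end"] = pd.to_datetime(out["end"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)
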