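"""Report assembly: difference statistics, daily rates and output tables.

Reported per-capita exposures are rounded to one decimal, round-half-up,
only after all aggregation; relative differences use the child group as
denominator ((adolescent - child) / child x 100), which is the convention
that reproduces every printed table value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import ReportError, ValidationError
from .exposure import ADOLESCENT, CHILD, ExposureEstimate


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (0.05 -> 0.1; -0.05 -> -0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReportConfig:
    rounding: int = 1
    days_in_period: int = 365
    station_count: Optional[int] = None

    def __post_init__(self) -> None:
        if self.rounding < 0:
            raise ValidationError("rounding must be >= 0")
        if self.days_in_period <= 0:
            raise ValidationError("days_in_period must be positive")
        if self.station_count is not None and self.station_count <= 0:
            raise ValidationError("station_count must be positive")


@dataclass(frozen=True)
class DifferenceRow:
    """Adolescent-vs-child contrast for one reported cell.

    ``relative_diff`` is None (undefined) when the child exposure is zero.
    """

    slice: str
    child_exposure: float
    adolescent_exposure: float
    absolute_diff: float
    relative_diff: Optional[float]

    @property
    def relative_undefined(self) -> bool:
        return self.relative_diff is None


def difference_row(
    child: float,
    adolescent: float,
    slice: str = "total",
    rounding: int = 1,
) -> DifferenceRow:
    """Absolute (adolescent - child) and relative (/ child x 100) difference.

    Computed from the unrounded inputs; rounding is applied last.

    >>> difference_row(2234.4, 1631.7).absolute_diff
    -602.7
    >>> difference_row(2234.4, 1631.7).relative_diff
    -27.0
    """
    if child < 0 or adolescent < 0:
        raise ValidationError("exposures must be non-negative")
    absolute = adolescent - child
    relative = None if child == 0 else absolute / child * 100.0
    return DifferenceRow(
        slice=slice,
        child_exposure=round_half_up(child, rounding),
        adolescent_exposure=round_half_up(adolescent, rounding),
        absolute_diff=round_half_up(absolute, rounding),
        relative_diff=None if relative is None else round_half_up(relative, rounding),
    )


def daily_rate(annual_exposure: float, config: ReportConfig = ReportConfig()) -> float:
    """Ads/person/day from an annual per-capita exposure.

    >>> daily_rate(2234.4)
    6.1
    """
    if annual_exposure < 0:
        raise ValidationError("annual_exposure must be >= 0")
    return round_half_up(annual_exposure / config.days_in_period, config.rounding)


def coverage_share(coded_frequency: float, total_frequency: float,
                   rounding: int = 1) -> float:
    """Percent of total weighted frequency covered by the content analysis.

    >>> coverage_share(1_670_912, 1_720_673)
    97.1
    """
    if total_frequency <= 0:
        raise ReportError("total frequency must be positive")
    if coded_frequency > total_frequency:
        raise ReportError("coded frequency exceeds total frequency")
    return round_half_up(coded_frequency / total_frequency * 100.0, rounding)


# ---------------------------------------------------------------------------
# Table assembly
# ---------------------------------------------------------------------------

def _exposure_maps(
    estimates: Sequence[ExposureEstimate],
) -> tuple[dict[str, float], dict[str, float]]:
    child: dict[str, float] = {}
    adolescent: dict[str, float] = {}
    for e in estimates:
        if e.group == CHILD:
            child[e.slice[1]] = e.exposure
        elif e.group == ADOLESCENT:
            adolescent[e.slice[1]] = e.exposure
    return child, adolescent


def _difference_frame(
    rows: Sequence[str],
    child: Mapping[str, float],
    adolescent: Mapping[str, float],
    frequency: Optional[Mapping[str, float]],
    freq_denominator: Optional[float],
    config: ReportConfig,
) -> pd.DataFrame:
    recs = []
    for r in rows:
        c = float(child.get(r, 0.0))
        a = float(adolescent.get(r, 0.0))
        d = difference_row(c, a, slice=r, rounding=config.rounding)
        rec: dict[str, object] = {"slice": r}
        if frequency is not None:
            f = float(frequency.get(r, 0.0))
            rec["frequency"] = int(round(f))
            if freq_denominator:
                rec["freq_percent"] = round_half_up(
                    f / freq_denominator * 100.0, config.rounding
                )
        rec.update(
            children=d.child_exposure,
            adolescents=d.adolescent_exposure,
            absolute_diff=d.absolute_diff,
            relative_diff=d.relative_diff,
        )
        recs.append(rec)
    return pd.DataFrame(recs).set_index("slice")


def station_table(
    estimates: Sequence[ExposureEstimate],
    freq_by_station: Mapping[str, float],
    config: ReportConfig = ReportConfig(),
) -> pd.DataFrame:
    """Per-station exposure table with total and per-station-average rows.

    ``estimates`` must be station-sliced and cover both age groups; every
    station in the frequency map needs estimates and vice versa.
    """
    child, adolescent = _exposure_maps(estimates)
    stations = sorted(set(child) | set(adolescent))
    missing = set(freq_by_station) ^ set(stations)
    if missing:
        raise ReportError(f"stations missing from estimates or frequency: {sorted(missing)}")
    freq_total = float(sum(freq_by_station.values()))
    table = _difference_frame(
        stations, child, adolescent, freq_by_station, freq_total, config
    )
    # totals from unrounded per-station values (stations partition exposure)
    c_tot = sum(child.values())
    a_tot = sum(adolescent.values())
    d = difference_row(c_tot, a_tot, rounding=config.rounding)
    n_st = config.station_count or len(stations)
    d_avg = difference_row(c_tot / n_st, a_tot / n_st, rounding=config.rounding)
    table.loc["total"] = {
        "frequency": int(round(freq_total)),
        "freq_percent": 100.0,
        "children": d.child_exposure,
        "adolescents": d.adolescent_exposure,
        "absolute_diff": d.absolute_diff,
        "relative_diff": d.relative_diff,
    }
    table["freq_percent"] = table["freq_percent"].astype(float)
    table.loc["average_by_station"] = {
        "frequency": round_half_up(freq_total / n_st, 0),
        "freq_percent": float("nan"),
        "children": d_avg.child_exposure,
        "adolescents": d_avg.adolescent_exposure,
        "absolute_diff": d_avg.absolute_diff,
        "relative_diff": d_avg.relative_diff,
    }
    return table


def category_table(
    estimates: Sequence[ExposureEstimate],
    frequency_table: pd.DataFrame,
    total_exposures: tuple[float, float],
    config: ReportConfig = ReportConfig(),
) -> pd.DataFrame:
    """Per-category exposure table.

    Category rows can sum above the total row: multi-category ads count once
    in the total but once per category in rows, so totals are supplied from
    the deduplicated estimates, not summed from rows.
    """
    child, adolescent = _exposure_maps(estimates)
    rows = [c for c in frequency_table.index]
    freq = frequency_table["weighted_frequency"].to_dict()
    freq_total = float(frequency_table.attrs.get("total", sum(freq.values())))
    table = _difference_frame(rows, child, adolescent, freq, freq_total, config)
    c_tot, a_tot = total_exposures
    d = difference_row(c_tot, a_tot, rounding=config.rounding)
    table.loc["total"] = {
        "frequency": int(round(freq_total)),
        "freq_percent": 100.0,
        "children": d.child_exposure,
        "adolescents": d.adolescent_exposure,
        "absolute_diff": d.absolute_diff,
        "relative_diff": d.relative_diff,
    }
    return table


def technique_table(
    estimates: Sequence[ExposureEstimate],
    freq_by_technique: Mapping[str, float],
    freq_total: float,
    config: ReportConfig = ReportConfig(),
) -> pd.DataFrame:
    """Per-technique exposure table (no total row: techniques overlap)."""
    child, adolescent = _exposure_maps(estimates)
    from .coding import TECHNIQUES

    rows = [t for t in TECHNIQUES if t in set(child) | set(adolescent)]
    return _difference_frame(
        rows, child, adolescent, freq_by_technique, freq_total, config
    )


def healthfulness_table(
    estimates: Sequence[ExposureEstimate],
    freq_by_label: Mapping[str, float],
    config: ReportConfig = ReportConfig(),
) -> pd.DataFrame:
    """Healthy/unhealthy exposure table; percents over classified ads only."""
    child, adolescent = _exposure_maps(estimates)
    rows = [l for l in ("healthy", "unhealthy") if l in set(child) | set(adolescent)]
    classified = float(sum(freq_by_label.get(l, 0.0) for l in ("healthy", "unhealthy")))
    if classified <= 0:
        raise ReportError("no classified advertisements")
    return _difference_frame(
        rows, child, adolescent, freq_by_label, classified, config
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def write_report_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path)


def read_report_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="slice")


def write_report_json(table: pd.DataFrame, path: str | Path) -> None:
    payload = {
        str(idx): {
            k: (None if pd.isna(v) else v) for k, v in row.items()
        }
        for idx, row in table.iterrows()
    }
    Path(path).write_text(json.dumps(payload, indent=1))
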