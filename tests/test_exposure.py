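import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adexpose.errors import ExposureError, ValidationError
from adexpose.exposure import (
    ADOLESCENT,
    CHILD,
    compute_weights,
    count_impressions,
    estimate_exposure,
    exposure_by_group,
    population_by_group,
    validate_viewing,
)

from conftest import brute_force_ledger, make_ad


def _panel(rows):
    return pd.DataFrame(rows, columns=["member_id", "age_group", "sex", "hh_band"])


class TestComputeWeights:
    def test_single_stratum(self):
        panel = _panel([(f"m{i}", CHILD, "f", "small") for i in range(10)])
        out = compute_weights(panel, {f"{CHILD}|f|small": 1000})
        assert (out["weight"] == 100.0).all()

    def test_panel_equals_population(self):
        panel = _panel([(f"m{i}", CHILD, "f", "small") for i in range(5)])
        out = compute_weights(panel, {f"{CHILD}|f|small": 5})
        assert (out["weight"] == 1.0).all()

    def test_two_strata_sum_to_population(self):
        panel = _panel(
            [(f"a{i}", CHILD, "f", "small") for i in range(6)]
            + [(f"b{i}", ADOLESCENT, "m", "small") for i in range(4)]
        )
        pops = {f"{CHILD}|f|small": 600, f"{ADOLESCENT}|m|small": 400}
        out = compute_weights(panel, pops)
        assert set(out["weight"]) == {100.0}
        assert out["weight"].sum() == 1000.0

    def test_empty_stratum_listed(self):
        panel = _panel([("m0", CHILD, "f", "small")])
        with pytest.raises(ExposureError, match="adolescent_12_17"):
            compute_weights(
                panel,
                {f"{CHILD}|f|small": 10, f"{ADOLESCENT}|m|small": 10},
            )

    def test_population_by_group_aggregates(self):
        pops = {
            f"{CHILD}|f|small": 10,
            f"{CHILD}|m|small": 15,
            f"{ADOLESCENT}|f|small": 7,
        }
        assert population_by_group(pops) == {CHILD: 25, ADOLESCENT: 7}


def _viewing(rows):
    df = pd.DataFrame(rows, columns=["member_id", "station", "start", "end"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


def _airings(rows):
    df = pd.DataFrame(rows, columns=["station", "start", "ad_id"])
    df["start"] = pd.to_datetime(df["start"])
    return df


ONE_PRODUCT_AD = {"A": make_ad("A", ["milk"])}


class TestCountImpressions:
    def test_all_day_watcher_catches_airing(self):
        viewing = _viewing([("m0", "S", "2019-01-01 00:00", "2019-01-02 00:00")])
        airings = _airings([("S", "2019-01-01 12:00", "A")])
        ledger = count_impressions(airings, ONE_PRODUCT_AD, viewing)
        assert len(ledger) == 1
        assert ledger.loc[0, "product_weight"] == 1

    def test_airing_at_interval_end_excluded(self):
        viewing = _viewing([("m0", "S", "2019-01-01 10:00", "2019-01-01 11:00")])
        airings = _airings([("S", "2019-01-01 11:00", "A")])
        assert len(count_impressions(airings, ONE_PRODUCT_AD, viewing)) == 0

    def test_airing_at_interval_start_included(self):
        viewing = _viewing([("m0", "S", "2019-01-01 10:00", "2019-01-01 11:00")])
        airings = _airings([("S", "2019-01-01 10:00", "A")])
        assert len(count_impressions(airings, ONE_PRODUCT_AD, viewing)) == 1

    def test_wrong_station_no_impression(self):
        viewing = _viewing([("m0", "T", "2019-01-01 00:00", "2019-01-02 00:00")])
        airings = _airings([("S", "2019-01-01 12:00", "A")])
        assert len(count_impressions(airings, ONE_PRODUCT_AD, viewing)) == 0

    def test_unknown_ad_rejected(self):
        viewing = _viewing([("m0", "S", "2019-01-01 00:00", "2019-01-02 00:00")])
        airings = _airings([("S", "2019-01-01 12:00", "ghost")])
        with pytest.raises(ExposureError, match="ghost"):
            count_impressions(airings, ONE_PRODUCT_AD, viewing)

    def test_invalid_interval_rejected(self):
        viewing = _viewing([("m0", "S", "2019-01-01 10:00", "2019-01-01 09:00")])
        with pytest.raises(ValidationError):
            validate_viewing(viewing)

    def test_cross_station_overlap_rejected(self):
        viewing = _viewing(
            [
                ("m0", "S", "2019-01-01 10:00", "2019-01-01 11:00"),
                ("m0", "T", "2019-01-01 10:30", "2019-01-01 11:30"),
            ]
        )
        with pytest.raises(ValidationError, match="overlap"):
            validate_viewing(viewing)

    def test_matches_brute_force_on_random_fixture(self):
        rng = np.random.default_rng(3)
        stations = ["S0", "S1", "S2"]
        ads = {"A": make_ad("A", ["milk", "cheese"]), "B": make_ad("B", ["cakes"])}
        airings = _airings(
            [
                (
                    stations[rng.integers(3)],
                    pd.Timestamp("2019-01-01") + pd.Timedelta(minutes=int(rng.integers(0, 1440))),
                    ["A", "B"][rng.integers(2)],
                )
                for _ in range(25)
            ]
        )
        rows = []
        for m in range(8):
            # disjoint slots per member: no overlap by construction
            t = 0
            while t < 1380:
                dur = int(rng.integers(20, 120))
                rows.append(
                    (
                        f"m{m}",
                        stations[rng.integers(3)],
                        pd.Timestamp("2019-01-01") + pd.Timedelta(minutes=t),
                        pd.Timestamp("2019-01-01") + pd.Timedelta(minutes=min(t + dur, 1440)),
                    )
                )
                t += dur + int(rng.integers(0, 60))
        viewing = _viewing(rows)
        ledger = count_impressions(airings, ads, viewing)
        got = sorted(zip(ledger["member_id"], ledger["airing_idx"]))
        assert got == brute_force_ledger(airings, ads, viewing)


class TestEstimateExposure:
    def _setup(self):
        panel = compute_weights(
            _panel([("m0", CHILD, "f", "small"), ("m1", CHILD, "m", "small")]),
            {f"{CHILD}|f|small": 1, f"{CHILD}|m|small": 1},
        )
        viewing = _viewing(
            [
                ("m0", "S", "2019-01-01 00:00", "2019-01-02 00:00"),
                ("m1", "S", "2019-01-01 00:00", "2019-01-02 00:00"),
            ]
        )
        airings = _airings([("S", "2019-01-01 12:00", "A")])
        ledger = count_impressions(airings, ONE_PRODUCT_AD, viewing)
        return ledger, panel

    def test_impressions_equal_population_gives_exposure_one(self):
        ledger, panel = self._setup()
        (est,) = estimate_exposure(ledger, panel, {CHILD: 2})
        assert est.impressions == 2.0
        assert est.grp == pytest.approx(100.0)
        assert est.exposure == pytest.approx(1.0)

    def test_grp_exposure_invariant(self, tiny_market):
        m = tiny_market
        ledger = count_impressions(m.airings, m.ads, m.viewing)
        for est in estimate_exposure(ledger, m.panel, m.population_by_group, "station"):
            assert est.grp == pytest.approx(est.impressions / est.population * 100)
            assert est.exposure == pytest.approx(est.grp / 100)

    def test_station_partition_additivity(self, sampled_market):
        m = sampled_market
        ledger = count_impressions(m.airings, m.ads, m.viewing)
        pbg = m.population_by_group
        total = exposure_by_group(estimate_exposure(ledger, m.panel, pbg, "total"))
        stations = exposure_by_group(estimate_exposure(ledger, m.panel, pbg, "station"))
        for g in total:
            assert sum(stations[g].values()) == pytest.approx(total[g]["total"])

    def test_category_super_additivity(self, sampled_market):
        m = sampled_market
        ledger = count_impressions(m.airings, m.ads, m.viewing)
        pbg = m.population_by_group
        brand_ads = {a for a in m.ads if m.ads[a].is_brand_ad}
        nonbrand = ledger[~ledger["ad_id"].isin(brand_ads)]
        total = exposure_by_group(estimate_exposure(nonbrand, m.panel, pbg, "total"))
        cats = exposure_by_group(
            estimate_exposure(ledger, m.panel, pbg, "category",
                              ads=m.ads, catmap=m.catmap)
        )
        # multi-category ads count once per category but once in the total
        for g in total:
            assert sum(cats[g].values()) >= total[g]["total"] - 1e-9

    def test_scale_equivariance(self):
        ledger, panel = self._setup()
        (base,) = estimate_exposure(ledger, panel, {CHILD: 2})
        doubled = panel.copy()
        doubled["weight"] = doubled["weight"] * 2
        (scaled,) = estimate_exposure(ledger, doubled, {CHILD: 4})
        assert scaled.grp == pytest.approx(base.grp)
        assert scaled.exposure == pytest.approx(base.exposure)

    def test_zero_population_rejected(self):
        ledger, panel = self._setup()
        with pytest.raises(ExposureError):
            estimate_exposure(ledger, panel, {CHILD: 0})

    def test_interval_split_invariance(self):
        ads = {"A": make_ad("A", ["milk"]), "B": make_ad("B", ["cakes"])}
        airings = _airings(
            [("S", "2019-01-01 08:30", "A"), ("S", "2019-01-01 15:00", "B")]
        )
        panel = compute_weights(
            _panel([("m0", CHILD, "f", "small")]), {f"{CHILD}|f|small": 3}
        )
        whole = _viewing([("m0", "S", "2019-01-01 08:00", "2019-01-01 16:00")])
        split = _viewing(
            [
                ("m0", "S", "2019-01-01 08:00", "2019-01-01 09:45"),
                ("m0", "S", "2019-01-01 09:45", "2019-01-01 12:00"),
                ("m0", "S", "2019-01-01 12:00", "2019-01-01 16:00"),
            ]
        )
        e1 = estimate_exposure(
            count_impressions(airings, ads, whole), panel, {CHILD: 3}
        )[0]
        e2 = estimate_exposure(
            count_impressions(airings, ads, split), panel, {CHILD: 3}
        )[0]
        assert e1.exposure == pytest.approx(e2.exposure)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(1, 5), st.integers(1, 500))
    def test_scale_equivariance_property(self, c, pop):
        ledger, panel = self._setup()
        (base,) = estimate_exposure(ledger, panel, {CHILD: pop})
        scaled_panel = panel.copy()
        scaled_panel["weight"] = scaled_panel["weight"] * c
        (scaled,) = estimate_exposure(ledger, scaled_panel, {CHILD: pop * c})
        assert scaled.exposure == pytest.approx(base.exposure)
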