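import numpy as np
import pandas as pd
import pytest

from adexpose.errors import ConfigError
from adexpose.exposure import (
    CHILD,
    count_impressions,
    estimate_exposure,
    exposure_by_group,
)
from adexpose.simulate import (
    MarketConfig,
    ViewingParams,
    compute_ground_truth,
    generate_market,
    load_market_config,
)

from conftest import TINY_POP, brute_force_group_exposure, make_ad


class TestConfigValidation:
    def test_default_config_valid(self):
        MarketConfig().validate()

    @pytest.mark.parametrize(
        "kwargs, field",
        [
            ({"n_stations": 0}, "n_stations"),
            ({"n_days": 0}, "n_days"),
            ({"category_mix": {"snacks": 0.5}}, "category_mix"),
            ({"products_per_ad_dist": {1: 0.5}}, "products_per_ad_dist"),
            ({"p_exceeds_threshold": 1.5}, "p_exceeds_threshold"),
        ],
    )
    def test_invalid_field_named(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            MarketConfig(**kwargs).validate()

    def test_panel_larger_than_population_rejected(self):
        cfg = MarketConfig(
            population_by_stratum={"child_2_11|f|small": 5},
            panel_size_by_stratum={"child_2_11|f|small": 6},
            viewing_model_params={"child_2_11": ViewingParams(100.0)},
        )
        with pytest.raises(ConfigError, match="panel_size_by_stratum"):
            cfg.validate()

    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text(
            "n_stations: 2\nn_days: 3\nn_airings: 50\nn_unique_ads: 10\n"
            "population_by_stratum:\n  'child_2_11|f|small': 10\n"
            "panel_size_by_stratum:\n  'child_2_11|f|small': 5\n"
            "viewing_model_params:\n  child_2_11:\n    mean_daily_minutes: 90\n"
            "seed: 3\n"
        )
        cfg = load_market_config(path)
        assert cfg.n_stations == 2
        assert cfg.viewing_model_params["child_2_11"].mean_daily_minutes == 90.0


class TestGenerateMarket:
    def test_same_seed_bit_identical(self):
        cfg = MarketConfig(seed=4, n_days=3, n_airings=200, n_unique_ads=20,
                           population_by_stratum=TINY_POP,
                           panel_size_by_stratum={k: 5 for k in TINY_POP})
        m1, m2 = generate_market(cfg), generate_market(cfg)
        pd.testing.assert_frame_equal(m1.airings, m2.airings)
        pd.testing.assert_frame_equal(m1.panel, m2.panel)
        pd.testing.assert_frame_equal(m1.viewing, m2.viewing)
        pd.testing.assert_frame_equal(m1.products, m2.products)
        assert m1.truth.by_group == m2.truth.by_group
        assert m1.ad_labels == m2.ad_labels

    def test_referential_integrity(self, tiny_market):
        m = tiny_market
        assert set(m.airings["ad_id"]) <= set(m.ads)
        assert set(m.viewing["member_id"]) <= set(m.panel["member_id"])
        assert set(m.viewing["station"]) <= set(m.stations)
        assert set(m.airings["station"]) <= set(m.stations)

    def test_panel_weights_sum_to_population(self, sampled_market):
        m = sampled_market
        assert m.panel["weight"].sum() == pytest.approx(
            sum(m.population_by_stratum.values())
        )

    def test_zero_airings_zero_truth(self):
        cfg = MarketConfig(seed=0, n_airings=0, n_days=2,
                           population_by_stratum=TINY_POP,
                           panel_size_by_stratum={k: 5 for k in TINY_POP})
        m = generate_market(cfg)
        assert all(v == 0.0 for v in m.truth.by_group.values())

    def test_truth_station_slices_sum_to_total(self, tiny_market):
        m = tiny_market
        for g, total in m.truth.by_group.items():
            st = m.truth.by_group_slice[g]["station"]
            assert sum(st.values()) == pytest.approx(total)

    def test_save_round_trips_text_files(self, tiny_market, tmp_path):
        from adexpose.exposure import read_panel_csv, read_viewing_csv
        from adexpose.ingest import ads_from_json, read_airings_csv

        m = tiny_market
        m.save(tmp_path)
        airings = read_airings_csv(tmp_path / "airings.csv")
        assert len(airings) == len(m.airings)
        ads = ads_from_json(tmp_path / "ads.json")
        assert set(ads) == set(m.ads)
        assert ads["AD0000"].products == m.ads["AD0000"].products
        panel = read_panel_csv(tmp_path / "panel.csv")
        assert len(panel) == len(m.panel)
        viewing = read_viewing_csv(tmp_path / "viewing.csv")
        assert len(viewing) == len(m.viewing)


class TestGroundTruth:
    def _persons(self, n=1, group=CHILD):
        return pd.DataFrame(
            {"member_id": [f"m{i}" for i in range(n)], "age_group": group}
        )

    def test_one_person_one_two_product_airing(self):
        ads = {"A": make_ad("A", ["milk", "cheese"])}
        airings = pd.DataFrame(
            {"station": ["S"], "start": [pd.Timestamp("2019-01-01 12:00")],
             "ad_id": ["A"]}
        )
        viewing = pd.DataFrame(
            {"member_id": ["m0"], "station": ["S"],
             "start": [pd.Timestamp("2019-01-01 00:00")],
             "end": [pd.Timestamp("2019-01-02 00:00")]}
        )
        truth = compute_ground_truth(airings, ads, viewing, self._persons())
        assert truth.by_group[CHILD] == pytest.approx(2.0)

    def test_full_coverage_caps_at_three(self):
        ads = {"A": make_ad("A", ["milk", "cheese", "yogurt", "cakes"])}
        airings = pd.DataFrame(
            {"station": ["S"], "start": [pd.Timestamp("2019-01-01 12:00")],
             "ad_id": ["A"]}
        )
        viewing = pd.DataFrame(
            {"member_id": ["m0", "m1"], "station": ["S", "S"],
             "start": [pd.Timestamp("2019-01-01 00:00")] * 2,
             "end": [pd.Timestamp("2019-01-02 00:00")] * 2}
        )
        truth = compute_ground_truth(airings, ads, viewing, self._persons(2))
        assert truth.by_group[CHILD] == pytest.approx(3.0)

    def test_nobody_watching(self):
        ads = {"A": make_ad("A", ["milk"])}
        airings = pd.DataFrame(
            {"station": ["S"], "start": [pd.Timestamp("2019-01-01 12:00")],
             "ad_id": ["A"]}
        )
        viewing = pd.DataFrame(columns=["member_id", "station", "start", "end"])
        truth = compute_ground_truth(airings, ads, viewing, self._persons())
        assert truth.by_group[CHILD] == 0.0

    def test_matches_brute_force_double_loop(self):
        cfg = MarketConfig(
            seed=21, n_stations=2, n_days=2, n_airings=60, n_unique_ads=12,
            population_by_stratum={"child_2_11|f|small": 12,
                                   "adolescent_12_17|m|small": 8},
            panel_size_by_stratum={"child_2_11|f|small": 12,
                                   "adolescent_12_17|m|small": 8},
        )
        m = generate_market(cfg)
        oracle = brute_force_group_exposure(
            m.airings, m.ads, m.population_viewing,
            m.persons[["member_id", "age_group"]],
        )
        for g, v in oracle.items():
            assert m.truth.by_group[g] == pytest.approx(v)

    def test_estimator_equals_truth_when_panel_is_population(self, tiny_market):
        m = tiny_market
        assert np.allclose(m.panel["weight"], 1.0)
        ledger = count_impressions(m.airings, m.ads, m.viewing)
        est = exposure_by_group(
            estimate_exposure(ledger, m.panel, m.population_by_group, "total")
        )
        for g, v in m.truth.by_group.items():
            assert est[g]["total"] == pytest.approx(v, rel=1e-12)

    def test_truth_json_round_trip(self, tiny_market, tmp_path):
        from adexpose.simulate import GroundTruth

        path = tmp_path / "truth.json"
        tiny_market.truth.to_json(path)
        loaded = GroundTruth.from_json(path)
        assert loaded.by_group == pytest.approx(tiny_market.truth.by_group)
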