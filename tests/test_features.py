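"""Feature engineering: outlier filtering, valence indices, feeder
aggregation, feeder rank and the assembled sow-period table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sow_welfare.features import (
    DataError,
    aggregate_feeder,
    build_feature_table,
    compute_feeder_rank,
    compute_index,
    filter_visits,
)


def _visits(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "sow_id", "group_id", "period", "day",
            "start_time", "duration_min", "feed_g", "nutritive",
        ],
    )


class TestFilterVisits:
    def test_six_hour_threshold_boundary(self):
        v = _visits(
            [
                ("X", "G", 1, 1, 0.0, 354.0, 100.0, True),
                ("X", "G", 1, 1, 400.0, 361.0, 100.0, True),
            ]
        )
        out = filter_visits(v)
        assert out["duration_min"].tolist() == [354.0]

    def test_empty_input(self):
        assert len(filter_visits(_visits([]))) == 0

    def test_exact_outlier_count_removed(self):
        rng = np.random.default_rng(0)
        durations = rng.uniform(0, 300, size=100_000)
        idx = rng.choice(100_000, size=7, replace=False)
        durations[idx] = rng.uniform(361, 500, size=7)
        v = _visits(
            [("X", "G", 1, 1, 0.0, d, 0.0, False) for d in durations]
        )
        assert len(filter_visits(v)) == 100_000 - 7

    def test_negative_duration_raises(self):
        with pytest.raises(DataError):
            filter_visits(_visits([("X", "G", 1, 1, 0.0, -1.0, 0.0, False)]))

    @given(
        st.lists(st.floats(min_value=0, max_value=800, allow_nan=False), max_size=30)
    )
    def test_filtering_is_idempotent(self, durations):
        v = _visits([("X", "G", 1, 1, 0.0, d, 0.0, False) for d in durations])
        once = filter_visits(v)
        twice = filter_visits(once)
        pd.testing.assert_frame_equal(once, twice)


class TestComputeIndex:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [(10, 10, 0.0), (1, 9, -0.8), (0, 0, 0.0), (5, 0, 1.0), (0, 3, -1.0)],
    )
    def test_known_values(self, pos, neg, expected):
        assert compute_index(pos, neg) == pytest.approx(expected)

    def test_negative_input_raises(self):
        with pytest.raises(DataError):
            compute_index(-1, 2)

    @given(
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    def test_antisymmetry_and_bounds(self, pos, neg):
        v = compute_index(pos, neg)
        assert -1.0 <= v <= 1.0
        assert compute_index(neg, pos) == pytest.approx(-v)


class TestAggregateFeeder:
    def test_hand_computed_mixture(self):
        v = _visits(
            [
                ("X", "G", 1, 1, 10.0, 30.0, 500.0, True),
                ("X", "G", 1, 2, 20.0, 40.0, 500.0, True),
                ("X", "G", 1, 1, 100.0, 5.0, 0.0, False),
            ]
        )
        agg = aggregate_feeder(v, "X", 1)
        assert agg == {
            "nb_nv": 2, "time_nv": 70.0, "avg_nv": 35.0,
            "nb_nnv": 1, "time_nnv": 5.0, "avg_nnv": 5.0,
        }

    def test_no_visits_all_zero(self):
        agg = aggregate_feeder(_visits([]), "X", 1)
        assert all(v == 0 for v in agg.values())

    def test_nonnutritive_only(self):
        v = _visits(
            [("X", "G", 1, 1, t, 6.0, 0.0, False) for t in (10.0, 50.0, 90.0, 130.0)]
        )
        agg = aggregate_feeder(v, "X", 1)
        assert (agg["nb_nnv"], agg["time_nnv"], agg["avg_nnv"]) == (4, 24.0, 6.0)
        assert (agg["nb_nv"], agg["time_nv"], agg["avg_nv"]) == (0, 0.0, 0.0)


class TestFeederRank:
    def test_order_statistics_over_two_days(self):
        rows = []
        for day in (1, 2):
            rows += [
                ("A", "G", 1, day, 5.0, 10.0, 100.0, True),
                ("B", "G", 1, day, 20.0, 10.0, 100.0, True),
                ("C", "G", 1, day, 60.0, 10.0, 100.0, True),
            ]
        ranks = compute_feeder_rank(_visits(rows), "G", 1)
        assert ranks.to_dict() == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_single_sow_rank_one(self):
        v = _visits([("A", "G", 1, 1, 5.0, 10.0, 100.0, True)])
        assert compute_feeder_rank(v, "G", 1).to_dict() == {"A": 1.0}

    def test_absent_sow_gets_n_plus_one(self):
        # 3 sows; A misses day 1 entirely, feeds first on day 2 -> (4+1)/2
        rows = [
            ("B", "G", 1, 1, 10.0, 5.0, 100.0, True),
            ("C", "G", 1, 1, 20.0, 5.0, 100.0, True),
            ("A", "G", 1, 2, 1.0, 5.0, 100.0, True),
            ("B", "G", 1, 2, 10.0, 5.0, 100.0, True),
            ("C", "G", 1, 2, 20.0, 5.0, 100.0, True),
        ]
        ranks = compute_feeder_rank(_visits(rows), "G", 1, roster=["A", "B", "C"])
        assert ranks["A"] == pytest.approx(2.5)

    def test_ranks_are_permutation_when_all_feed(self):
        rng = np.random.default_rng(4)
        sows = [f"S{i}" for i in range(6)]
        rows = [
            (s, "G", 1, 1, float(t), 5.0, 100.0, True)
            for s, t in zip(sows, rng.uniform(0, 500, size=6))
        ]
        ranks = compute_feeder_rank(_visits(rows), "G", 1)
        assert sorted(ranks.tolist()) == [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]


class TestBuildFeatureTable:
    def test_default_simulation_yields_complete_table(self, feature_table):
        assert len(feature_table) == 408
        idx = feature_table[["index_activity", "index_giving", "index_receiving"]]
        assert ((idx >= -1) & (idx <= 1)).all().all()

    def test_two_sow_fixture_computed_by_hand(self):
        visits = _visits(
            [
                ("X", "G", 1, 1, 10.0, 30.0, 500.0, True),
                ("X", "G", 1, 1, 200.0, 40.0, 600.0, True),
                ("X", "G", 1, 1, 300.0, 5.0, 0.0, False),
                ("X", "G", 1, 2, 20.0, 30.0, 500.0, True),
                ("Y", "G", 1, 1, 5.0, 20.0, 400.0, True),
                ("Y", "G", 1, 2, 50.0, 6.0, 0.0, False),
            ]
        )
        ethogram = pd.DataFrame(
            [
                {"sow_id": "X", "period": 1, "active_min": 300.0, "passive_min": 300.0,
                 "giv_pos": 9, "giv_neg": 1, "rec_pos": 0, "rec_neg": 0},
                {"sow_id": "Y", "period": 1, "active_min": 150.0, "passive_min": 450.0,
                 "giv_pos": 1, "giv_neg": 9, "rec_pos": 3, "rec_neg": 1},
            ]
        )
        postures = pd.DataFrame(
            [{"group_id": "G", "period": 1, "side_lying": 50.0, "ventral_lying": 20.0,
              "standing": 20.0, "sitting": 1.0, "eating": 3.0, "drinking": 0.5}]
        )
        schedule = pd.DataFrame(
            [{"group_id": "G", "period": 1, "week_type": "control", "event_type": ""}]
        )
        table = build_feature_table(visits, ethogram, postures, schedule)
        x = table[table["sow_id"] == "X"].iloc[0]
        y = table[table["sow_id"] == "Y"].iloc[0]
        assert x["index_activity"] == pytest.approx(0.0)
        assert x["index_giving"] == pytest.approx(0.8)
        assert x["index_receiving"] == pytest.approx(0.0)  # 0/0 convention
        assert (x["nb_nv"], x["time_nv"], x["avg_nv"]) == (3, 100.0, pytest.approx(100 / 3))
        assert (x["nb_nnv"], x["time_nnv"], x["avg_nnv"]) == (1, 5.0, 5.0)
        # day 1: Y first (05:00) then X; day 2: X only, Y absent -> rank 3
        assert x["rank_cat"] == pytest.approx(1.5)
        assert y["rank_cat"] == pytest.approx(2.0)
        assert y["index_activity"] == pytest.approx(-0.5)
        assert y["index_giving"] == pytest.approx(-0.8)
        assert y["index_receiving"] == pytest.approx(0.5)
        assert (y["nb_nv"], y["avg_nv"]) == (1, 20.0)
        assert (x["eating"], x["week_type"]) == (3.0, "control")

    def test_missing_ethogram_row_drops_record(self, caplog):
        visits = _visits(
            [
                ("X", "G", 1, 1, 10.0, 30.0, 500.0, True),
                ("Y", "G", 1, 1, 5.0, 20.0, 400.0, True),
            ]
        )
        ethogram = pd.DataFrame(
            [{"sow_id": "X", "period": 1, "active_min": 10.0, "passive_min": 10.0,
              "giv_pos": 1, "giv_neg": 1, "rec_pos": 1, "rec_neg": 1}]
        )
        postures = pd.DataFrame(
            [{"group_id": "G", "period": 1, "side_lying": 50.0, "ventral_lying": 20.0,
              "standing": 20.0, "sitting": 1.0, "eating": 3.0, "drinking": 0.5}]
        )
        schedule = pd.DataFrame(
            [{"group_id": "G", "period": 1, "week_type": "control", "event_type": ""}]
        )
        table = build_feature_table(visits, ethogram, postures, schedule)
        assert table["sow_id"].tolist() == ["X"]

    def test_balanced_ethogram_gives_zero_activity_index(self, default_dataset):
        ds = default_dataset
        eth = ds.ethogram.copy()
        eth.loc[eth.index[0], ["active_min", "passive_min"]] = 100.0, 100.0
        table = build_feature_table(ds.visits, eth, ds.postures, ds.schedule)
        sow, period = eth.loc[eth.index[0], ["sow_id", "period"]]
        row = table[(table["sow_id"] == sow) & (table["period"] == period)].iloc[0]
        assert row["index_activity"] == 0.0
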