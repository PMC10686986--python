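"""Generator calibration: latent-state frequencies, index convergence,
feeder/posture means, and reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from sow_welfare.features import compute_index
from sow_welfare.simgen import (
    DEFAULT_POSTURE_PARAMS,
    POSTURES,
    STATES,
    SimConfig,
    SimConfigError,
    generate_dataset,
    sample_state,
    simulate_ethogram,
    simulate_feeder_visits,
    simulate_postures,
)


@pytest.fixture()
def config():
    return SimConfig()


class TestSampleState:
    @pytest.mark.parametrize(
        "week_type,event_type,state,expected",
        [
            ("control", None, "gentle", 0.53),
            ("control", None, "aggressive", 0.25),
            ("event", "sound", "aggressive", 0.39),
            ("event", None, "gentle", 0.35),
        ],
    )
    def test_frequencies_match_configured_simplex(
        self, config, week_type, event_type, state, expected
    ):
        rng = np.random.default_rng(3)
        n = 100_000
        draws = [sample_state(week_type, event_type, config, rng) for _ in range(n)]
        freq = np.mean([d == state for d in draws])
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(freq - expected) < 3 * se

    def test_chi2_goodness_of_fit_not_rejected(self, config):
        rng = np.random.default_rng(11)
        n = 100_000
        draws = [sample_state("control", None, config, rng) for _ in range(n)]
        observed = [sum(d == s for d in draws) for s in STATES]
        expected = [config.state_probs_control[s] * n for s in STATES]
        _, p = sps.chisquare(observed, expected)
        assert p > 0.01

    def test_degenerate_simplex_is_deterministic(self):
        cfg = SimConfig(
            state_probs_control={"gentle": 1.0, "aggressive": 0.0, "scapegoat": 0.0}
        )
        rng = np.random.default_rng(0)
        assert all(
            sample_state("control", None, cfg, rng) == "gentle" for _ in range(50)
        )

    def test_event_modifier_overrides_event_probs(self, config):
        cfg = dataclasses.replace(
            config,
            event_modifiers={
                "cold": {"gentle": 0.0, "aggressive": 1.0, "scapegoat": 0.0}
            },
        )
        rng = np.random.default_rng(0)
        assert all(
            sample_state("event", "cold", cfg, rng) == "aggressive" for _ in range(50)
        )

    @pytest.mark.parametrize(
        "week_type,event_type",
        [("weekend", None), ("event", "earthquake"), ("control", "sound")],
    )
    def test_invalid_inputs_raise(self, config, week_type, event_type):
        with pytest.raises(SimConfigError):
            sample_state(week_type, event_type, config, np.random.default_rng(0))


class TestSimConfigValidation:
    def test_non_simplex_probs_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(state_probs_control={"gentle": 0.6, "aggressive": 0.6, "scapegoat": -0.2})

    def test_out_of_range_index_center_rejected(self):
        centers = {
            "gentle": (-0.18, 0.5, 0.0),
            "aggressive": (1.5, -0.8, -0.67),
            "scapegoat": (-0.14, 0.08, -0.75),
        }
        with pytest.raises(SimConfigError):
            SimConfig(index_centers=centers)


class TestEthogram:
    @pytest.mark.parametrize("state", STATES)
    def test_index_expectations_converge_to_centers(self, config, state):
        rng = np.random.default_rng(5)
        tallies = [simulate_ethogram(state, config, rng) for _ in range(10_000)]
        c_act, c_giv, c_rec = config.index_centers[state]
        act = np.mean(
            [compute_index(t.active_min, t.passive_min) for t in tallies]
        )
        giv = np.mean([compute_index(t.giv_pos, t.giv_neg) for t in tallies])
        rec = np.mean([compute_index(t.rec_pos, t.rec_neg) for t in tallies])
        assert abs(act - c_act) < 0.05
        assert abs(giv - c_giv) < 0.05
        assert abs(rec - c_rec) < 0.05  # scapegoat: within 0.05 of -0.75

    def test_zero_rates_give_zero_counts(self, config):
        cfg = dataclasses.replace(config, interaction_total_rate=0.0)
        t = simulate_ethogram("gentle", cfg, np.random.default_rng(0))
        assert (t.giv_pos, t.giv_neg, t.rec_pos, t.rec_neg) == (0, 0, 0, 0)

    def test_giving_index_closed_form_in_large_rate_limit(self, config):
        # aggressive rates are 1:9, so the index tends to (1-9)/(1+9) = -0.8
        cfg = dataclasses.replace(config, interaction_total_rate=2000.0)
        rates = cfg.interaction_rates("aggressive")
        assert rates["giv_pos"] / rates["giv_neg"] == pytest.approx(1 / 9)
        rng = np.random.default_rng(1)
        vals = [
            compute_index(t.giv_pos, t.giv_neg)
            for t in (simulate_ethogram("aggressive", cfg, rng) for _ in range(2000))
        ]
        assert np.mean(vals) == pytest.approx(-0.8, abs=0.005)


class TestFeederVisits:
    def test_aggressive_nutritive_count_matches_calibration(self, config):
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(1000):
            vs = simulate_feeder_visits("aggressive", "S1", 2, config, rng)
            counts.append(sum(v.nutritive for v in vs))
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 3.11) < 3 * se

    def test_gentle_nutritive_time_matches_calibration(self, config):
        rng = np.random.default_rng(8)
        times = []
        for _ in range(1000):
            vs = simulate_feeder_visits("gentle", "S1", 2, config, rng)
            times.append(sum(v.duration_min for v in vs if v.nutritive))
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(np.mean(times) - 80.6) < 3 * se

    def test_zero_visit_rate_gives_empty_list(self, config):
        params = {
            s: {"nb_nv": 0.0, "nb_nnv": 0.0, "time_nv": 0.0, "time_nnv": 0.0}
            for s in STATES
        }
        cfg = dataclasses.replace(config, feeder_params=params)
        assert simulate_feeder_visits("gentle", "S1", 2, cfg, np.random.default_rng(0)) == []

    def test_visits_are_physical(self, config):
        rng = np.random.default_rng(9)
        for state in STATES:
            for v in simulate_feeder_visits(state, "S1", 2, config, rng):
                assert v.duration_min >= 0
                assert 0 <= v.start_time < 1440
                assert v.nutritive == (v.feed_g > 0)


class TestPostures:
    def test_all_aggressive_group_eating_mean(self, config):
        rng = np.random.default_rng(10)
        vals = [
            simulate_postures(["aggressive"] * 17, config, rng)["eating"]
            for _ in range(1000)
        ]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 3.93) < 3 * se

    def test_zero_noise_returns_exact_budgets(self, config):
        cfg = dataclasses.replace(config, posture_noise_sd=0.0)
        out = simulate_postures(["gentle"] * 5, cfg, np.random.default_rng(0))
        for p in POSTURES:
            assert out[p] == pytest.approx(DEFAULT_POSTURE_PARAMS["gentle"][p])

    def test_mixed_group_is_the_mixture_mean(self, config):
        rng = np.random.default_rng(12)
        states = ["aggressive"] * 8 + ["gentle"] * 8
        vals = [simulate_postures(states, config, rng)["eating"] for _ in range(2000)]
        assert np.mean(vals) == pytest.approx((3.93 + 2.97) / 2, abs=0.05)

    def test_empty_group_raises(self, config):
        with pytest.raises(SimConfigError):
            simulate_postures([], config, np.random.default_rng(0))


class TestGenerateDataset:
    def test_same_seed_is_bit_identical(self):
        a = generate_dataset(SimConfig(seed=42))
        b = generate_dataset(SimConfig(seed=42))
        for name in ("visits", "ethogram", "postures", "registry", "schedule", "truth"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seeds_differ(self):
        a = generate_dataset(SimConfig(seed=1))
        b = generate_dataset(SimConfig(seed=2))
        assert not a.truth["state"].equals(b.truth["state"])

    def test_truth_row_count_is_sows_times_periods(self, default_dataset):
        assert len(default_dataset.truth) == 4 * 17 * 6

    def test_overall_gentle_fraction_between_week_type_targets(self, default_dataset):
        frac = (default_dataset.truth["state"] == "gentle").mean()
        assert 0.35 < frac < 0.53

    def test_event_type_present_iff_event_week(self, default_dataset):
        truth = default_dataset.truth
        assert (truth.loc[truth["week_type"] == "event", "event_type"] != "").all()
        assert (truth.loc[truth["week_type"] == "control", "event_type"] == "").all()

    def test_streams_are_physical(self, default_dataset):
        ds = default_dataset
        assert (ds.visits["duration_min"] >= 0).all()
        posture_cols = ds.postures.drop(columns=["group_id", "period"])
        assert ((posture_cols >= 0) & (posture_cols <= 100)).all().all()
        assert posture_cols.sum(axis=1).max() <= 100 + 1e-9
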