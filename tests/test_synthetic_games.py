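"""Synthetic season generator: moments, reproducibility, aggregation, calibration."""

import numpy as np
import pandas as pd
import pytest

from rule48.cohort_data import DenominatorKind
from rule48.synthetic_games import (
    HEAD_MECHANISMS,
    SeasonConfig,
    aggregate,
    calibration_study,
    paper_calibrated_configs,
    simulate_season,
)


def small_config(**overrides) -> SeasonConfig:
    base = dict(
        label="toy",
        n_games=400,
        incidence_per_game=0.25,
        characteristic_mixtures={
            "location": {"open ice": 0.4, "perimeter": 0.6},
            "zone": {"offensive": 0.3, "neutral": 0.2, "defensive": 0.5},
            "period": {"first": 0.5, "later": 0.5},
            "mechanism": {
                "none": 0.25,
                "body check body": 0.26,
                "shoulder": 0.34,
                "glove": 0.03,
                "arm": 0.12,
            },
            "position": {"forward": 0.65, "defense": 0.3, "goalie": 0.05},
        },
        lateral_given_head=0.7,
        puck_possession_rate=0.2,
        penalty_rate=0.27,
        video_rate=0.85,
        seed=123,
    )
    base.update(overrides)
    return SeasonConfig(**base)


class TestSimulateSeason:
    def test_zero_incidence_means_zero_events(self):
        table = simulate_season(small_config(incidence_per_game=0.0))
        assert int(table["event"].sum()) == 0
        assert len(table) == 400

    def test_identical_seeds_bit_identical_tables(self):
        a = simulate_season(small_config())
        b = simulate_season(small_config())
        pd.testing.assert_frame_equal(a, b)
        c = simulate_season(small_config(seed=124))
        assert not a.equals(c)

    def test_event_count_matches_binomial_moments(self):
        # 200 replicates at the pre-era scale: mean count within 3 SEs of n*p
        n_games, p, reps = 4920, 301 / 4920, 200
        counts = [
            int(simulate_season(
                small_config(n_games=n_games, incidence_per_game=p, seed=s)
            )["event"].sum())
            for s in range(reps)
        ]
        se = np.sqrt(n_games * p * (1 - p) / reps)
        assert np.mean(counts) == pytest.approx(301, abs=3 * se)

    def test_video_rate_matches_binomial_moments(self):
        table = simulate_season(small_config(n_games=20_000, video_rate=0.842))
        events = table[table["event"]]
        n = len(events)
        observed = events["video"].mean()
        assert observed == pytest.approx(0.842, abs=3 * np.sqrt(0.842 * 0.158 / n))

    def test_lateral_only_on_hits_to_head(self):
        table = simulate_season(small_config(n_games=5000))
        events = table[table["event"]]
        lateral_but_not_head = events["lateral"] & ~events["mechanism"].isin(
            HEAD_MECHANISMS
        )
        assert not lateral_but_not_head.any()

    def test_mixtures_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            small_config(
                characteristic_mixtures={
                    **small_config().characteristic_mixtures,
                    "zone": {"offensive": 0.5, "neutral": 0.2, "defensive": 0.5},
                }
            )

    def test_poisson_variant_allows_multiple_events_per_game(self):
        table = simulate_season(
            small_config(poisson_per_game=True, incidence_per_game=0.9, n_games=2000)
        )
        per_game = table[table["event"]].groupby("game").size()
        assert per_game.max() > 1


class TestAggregate:
    def test_counts_by_construction(self):
        table = simulate_season(small_config(n_games=2000))
        events = table[table["event"]]
        vid = events[events["video"]]
        counts, cohort = aggregate(table)
        by = {c.variable: c for c in counts}
        assert cohort.n_games == 2000
        assert cohort.n_concussions_total == len(events)
        assert cohort.n_concussions_video == len(vid)
        assert by["open ice"].numerator == int((vid["location"] == "open ice").sum())
        assert by["open ice"].denominator == len(vid)
        assert by["all body checks"].numerator == int((vid["mechanism"] != "none").sum())
        head = vid["mechanism"].isin(HEAD_MECHANISMS)
        assert by["body checks to head"].numerator == int(head.sum())
        assert by["lateral hit to head"].numerator == int(vid["lateral"].sum())
        assert all(
            c.denominator_kind is DenominatorKind.EVENTS_WITH_VIDEO for c in counts
        )

    def test_no_video_drops_proportions_with_warning(self):
        table = simulate_season(small_config(video_rate=0.0))
        with pytest.warns(UserWarning, match="no events with video"):
            counts, cohort = aggregate(table)
        assert counts == []
        assert cohort.n_concussions_video == 0
        assert cohort.n_concussions_total > 0

    def test_unknown_label_rejected(self):
        table = simulate_season(small_config(n_games=500))
        table.loc[table["event"], "zone"] = "parking lot"
        with pytest.raises(ValueError, match="parking lot"):
            aggregate(table)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate(pd.DataFrame())

    def test_proportions_converge_to_mixture_probabilities(self):
        # law of large numbers at 50k games: within 1 pp of the mixture
        config = small_config(n_games=50_000, video_rate=1.0, seed=7)
        counts, _ = aggregate(simulate_season(config))
        by = {c.variable: c for c in counts}
        checks = {
            "open ice": 0.4,
            "defensive": 0.5,
            "first period": 0.5,
            "forward": 0.65,
            "body checks to head": 0.34 + 0.03 + 0.12,
            "lateral hit to head": (0.34 + 0.03 + 0.12) * 0.7,
        }
        for variable, truth in checks.items():
            record = by[variable]
            assert record.numerator / record.denominator == pytest.approx(
                truth, abs=0.01
            ), variable


class TestPaperCalibratedConfigs:
    def test_cohort_scale_and_rates(self):
        pre, post = paper_calibrated_configs(seed=0)
        assert (pre.n_games, post.n_games) == (4920, 6232)
        assert pre.incidence_per_game == pytest.approx(301 / 4920)
        assert post.incidence_per_game == pytest.approx(516 / 6232)
        assert pre.video_rate == pytest.approx(231 / 301)
        assert post.video_rate == pytest.approx(457 / 516)
        # marginal structure mirrors the published tables
        assert pre.characteristic_mixtures["location"]["open ice"] == pytest.approx(
            108 / 231
        )
        assert post.lateral_given_head == pytest.approx(61 / 149)

    def test_roundtrip_feeds_pipeline_without_schema_errors(self):
        from rule48.cohort_data import read_counts, write_counts

        pre, _ = paper_calibrated_configs(seed=3)
        counts, cohort = aggregate(simulate_season(pre))
        assert len(counts) == 16
        assert all(0 <= c.numerator <= c.denominator for c in counts)
        assert cohort.n_concussions_video == counts[0].denominator

    def test_pipeline_recovers_configured_shift_at_paper_scale(self):
        # true lateral-hit shift between the calibrated cohorts, one replicate
        pre_cfg, post_cfg = paper_calibrated_configs(seed=5)
        p_head = lambda c: sum(
            c.characteristic_mixtures["mechanism"][m] for m in HEAD_MECHANISMS
        )
        truth = 100 * (
            p_head(post_cfg) * post_cfg.lateral_given_head
            - p_head(pre_cfg) * pre_cfg.lateral_given_head
        )
        report = calibration_study(pre_cfg, post_cfg, truth, n_reps=20, seed=6)
        assert abs(report.mean_bias) < 3.0  # documented skeptical shrinkage


class TestCalibrationStudy:
    def test_single_replicate_runs(self):
        pre, post = paper_calibrated_configs(seed=1)
        report = calibration_study(pre, post, true_diff=-15.0, n_reps=1, seed=2)
        assert report.n_reps == 1
        assert report.coverage_90 in (0.0, 1.0)
        assert report.estimates.shape == (1,)

    def test_invalid_rep_count_rejected(self):
        pre, post = paper_calibrated_configs(seed=1)
        with pytest.raises(ValueError):
            calibration_study(pre, post, 0.0, n_reps=0)
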