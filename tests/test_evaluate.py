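"""Scoring metrics, ΔT histograms and the sweep harness."""

import numpy as np
import pandas as pd
import pytest

from scorrflow import (
    GroundTruth,
    MatchSet,
    ScorrParams,
    SimulationConfig,
    delta_t_histogram,
    fold_increase,
    peak_tables,
    score_matches,
    scorr_colocalize,
    simulate_particles,
    sweep,
)


def empty_matchset(method="scorr"):
    cols = ["red_idx", "blue_idx", "red_t_center_ms", "blue_t_center_ms",
            "delta_t_ms", "pt_red_ms", "pt_blue_ms", "stage", "red_true_id",
            "blue_true_id", "red_brightness", "blue_brightness"]
    return MatchSet(pd.DataFrame(columns=cols), pd.DataFrame(), pd.DataFrame(), method)


def tiny_ground_truth(n):
    particles = pd.DataFrame(
        {
            "particle_id": np.arange(n),
            "speed_um_per_ms": 2.0,
            "t_red_ms": 10.0 * np.arange(n),
            "t_blue_ms": 10.0 * np.arange(n) + 7.5,
            "pt_red_ms": 0.5,
            "pt_blue_ms": 0.5,
            "brightness_class": "dim",
            "intensity": 1.0,
        }
    )
    return GroundTruth(particles=particles)


class TestScoreMatches:
    def test_perfect_matching(self, geom):
        config = SimulationConfig(arrival_rate=50.0, duration=10.0, pt_error_cv=0.0, seed=31)
        gt = simulate_particles(config)
        red, blue = peak_tables(gt)
        ms = scorr_colocalize(red, blue, geom, ScorrParams(w1=2.0, w2=2.0))
        report = score_matches(ms, gt)
        assert report.true_colocalized_pct == pytest.approx(100.0)
        assert report.mis_colocalized_pct == 0.0
        assert report.loss_pct == pytest.approx(0.0)
        assert report.histogram.counts.sum() == report.n_matches

    def test_empty_matchset_is_total_loss(self):
        report = score_matches(empty_matchset(), tiny_ground_truth(5))
        assert report.true_colocalized_pct == 0.0
        assert report.loss_pct == 100.0
        assert report.n_matches == 0

    def test_handmade_dim_bright_cross_pairing(self):
        # 4 particles, 3 correct pairs, 1 deliberate dim<->bright swap:
        # mis-colocalization = 1/4 = 25%
        gt = tiny_ground_truth(4)
        matches = pd.DataFrame(
            {
                "red_idx": [0, 1, 2, 3],
                "blue_idx": [0, 1, 3, 2],
                "red_t_center_ms": gt.particles.t_red_ms,
                "blue_t_center_ms": gt.particles.t_blue_ms,
                "delta_t_ms": [0.0, 0.0, 0.3, 0.3],
                "pt_red_ms": 0.5,
                "pt_blue_ms": 0.5,
                "stage": "fine",
                "red_true_id": [0, 1, 2, 3],
                "blue_true_id": [0, 1, 3, 2],
                "red_brightness": ["dim", "bright", "dim", "bright"],
                "blue_brightness": ["dim", "bright", "bright", "dim"],
            }
        )
        ms = MatchSet(matches, pd.DataFrame(), pd.DataFrame(), "scorr")
        report = score_matches(ms, gt)
        assert report.true_colocalized_pct == pytest.approx(50.0)
        assert report.wrong_colocalized_pct == pytest.approx(50.0)
        assert report.mis_colocalized_pct == pytest.approx(50.0)
        # a single cross-pairing among four particles
        one_swap = matches.iloc[[0, 1, 2]].copy()
        report = score_matches(MatchSet(one_swap, pd.DataFrame(), pd.DataFrame(), "scorr"), gt)
        assert report.mis_colocalized_pct == pytest.approx(25.0)

    def test_requires_ground_truth_ids(self):
        ms = empty_matchset()
        ms.matches = ms.matches.drop(columns=["red_true_id", "blue_true_id"])
        with pytest.raises(ValueError, match="true_particle_id"):
            score_matches(ms, tiny_ground_truth(3))


class TestDeltaTHistogram:
    def test_all_zero_delta_t(self):
        hist = delta_t_histogram(np.zeros(10), bin_width=0.25)
        assert hist.counts[0] == 10
        assert hist.fraction_within(0.25) == 1.0

    def test_uniform_mass(self):
        values = np.linspace(0.0, 4.0, 4001)
        hist = delta_t_histogram(values, bin_width=0.25)
        assert hist.fraction_within(0.5) == pytest.approx(0.125, abs=0.001)
        assert hist.counts.sum() == values.size

    def test_invalid_bin_width(self):
        with pytest.raises(ValueError):
            delta_t_histogram(np.zeros(1), bin_width=0.0)


class TestSweep:
    def test_single_cell_single_replicate(self):
        table = sweep(
            densities=(35.0,),
            bright_fractions=(0.5,),
            w1_values=(2.0,),
            w2_values=(2.0,),
            methods=("scorr",),
            replicates=1,
            seed=1,
            base_config=SimulationConfig(duration=5.0),
        )
        assert len(table) == 1
        assert table.method.iloc[0] == "scorr"

    def test_deterministic_under_seed(self):
        kwargs = dict(
            densities=(35.0,),
            bright_fractions=(0.5,),
            w2_values=(1.0, 4.0),
            replicates=2,
            seed=5,
            base_config=SimulationConfig(duration=5.0),
        )
        pd.testing.assert_frame_equal(sweep(**kwargs), sweep(**kwargs))

    def test_true_colocalization_non_increasing_as_w2_shrinks(self):
        table = sweep(
            densities=(252.0,),
            bright_fractions=(0.5,),
            w2_values=(0.25, 0.5, 1.0, 2.0, 4.0),
            methods=("scorr",),
            replicates=1,
            seed=2,
            base_config=SimulationConfig(duration=10.0),
        )
        by_w2 = table.sort_values("w2_ms")["true_colocalized_pct"].to_numpy()
        assert (np.diff(by_w2) >= 0).all()

    def test_fold_increase_at_least_one_at_narrow_w2(self):
        table = sweep(
            densities=(35.0,),
            bright_fractions=(0.5,),
            w2_values=(0.5, 1.0),
            replicates=1,
            seed=3,
            base_config=SimulationConfig(duration=20.0),
        )
        fi = fold_increase(table)
        assert (fi.fold >= 1.0).all()
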