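"""Transit-time colocalization: shifts, gating, conflict resolution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scorrflow import (
    LaserGeometry,
    ScorrParams,
    SimulationConfig,
    coarse_shift,
    find_lag,
    fine_shift,
    peak_tables,
    peaks_to_trace,
    predicted_travel_time,
    resolve_conflicts,
    scorr_colocalize,
    select_candidates,
    simulate_particles,
    xcorr_colocalize,
)

from conftest import make_peaks


def naive_scorr(red, blue, geom, w1, w2, tie_tol=1e-6):
    """Independent plain-Python reference: brute-force candidate scan,
    then repeated extraction of the globally best proposal (min ΔT, ties
    by least relative transit-time change)."""
    red = red.sort_values(["t_center_ms", "pt_ms", "height"], ignore_index=True)
    blue = blue.sort_values(["t_center_ms", "pt_ms", "height"], ignore_index=True)
    props = []
    for i, rp in red.iterrows():
        t_pred_c = rp.t_center_ms + rp.pt_ms * geom.dx3 / geom.dx2
        for j, bp in blue.iterrows():
            if abs(bp.t_center_ms - t_pred_c) <= w1:
                v1 = geom.dx1 / bp.pt_ms
                v2 = geom.dx2 / rp.pt_ms
                t_pred = rp.t_center_ms + geom.dx3 / (0.5 * (v1 + v2))
                dt = abs(bp.t_center_ms - t_pred)
                if dt <= w2:
                    rel = abs(bp.pt_ms - rp.pt_ms) / rp.pt_ms
                    props.append((dt, rel, i, j))
    chosen = set()
    while props:
        dt, rel, i, j = min(props, key=lambda p: (round(p[0] / tie_tol), p[1], p[0]))
        chosen.add((i, j))
        props = [p for p in props if p[2] != i and p[3] != j]
    return chosen


class TestShifts:
    def test_coarse_shift_fast_particle(self, geom):
        # v = 3 um/ms crossing the 1 um red beam in 1/3 ms: travels the
        # 15 um gap in 5 ms
        assert coarse_shift(100.0, 1.0 / 3.0, geom) == pytest.approx(105.0)

    def test_coarse_shift_slow_particle(self, geom):
        assert coarse_shift(100.0, 1.0, geom) == pytest.approx(115.0)

    def test_fine_equals_coarse_for_constant_speed(self, geom):
        t = fine_shift(50.0, 0.5, 0.5, geom)
        assert t == pytest.approx(coarse_shift(50.0, 0.5, geom))

    def test_fine_shift_average_velocity(self, geom):
        # v2 = 2, v1 = 3 -> v_avg = 2.5 -> PT3 = 15 / 2.5 = 6 ms
        assert predicted_travel_time(geom, 0.5, 1.0 / 3.0) == pytest.approx(6.0)

    def test_harmonic_average_option(self, geom):
        pt3 = predicted_travel_time(geom, 0.5, 1.0 / 3.0, velocity_average="harmonic")
        assert pt3 == pytest.approx(15.0 / 2.4)

    def test_nonpositive_transit_time_rejected(self, geom):
        with pytest.raises(ValueError):
            coarse_shift(1.0, 0.0, geom)
        with pytest.raises(ValueError):
            fine_shift(1.0, 0.5, -0.2, geom)


class TestSelectCandidates:
    def test_exact_hit_and_boundary(self, geom):
        blue = make_peaks([105.0, 107.0 + 1e-9], [0.5, 0.5], channel="blue")
        cand = select_candidates(105.0, blue, w1=2.0)
        assert cand["t_center_ms"].tolist() == [105.0]
        assert cand["delta_t_ms"].iloc[0] == 0.0

    def test_dense_cluster_ordered_by_delta_t(self, geom):
        blue = make_peaks([104.2, 105.4, 106.1], [0.5] * 3, channel="blue")
        cand = select_candidates(105.0, blue, w1=2.0)
        # brute-force scan agrees
        expected = sorted([104.2, 105.4, 106.1], key=lambda t: abs(t - 105.0))
        assert cand["t_center_ms"].tolist() == expected


class TestResolveConflicts:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["red_idx", "blue_idx", "delta_t_ms", "rel_pt_change"])

    def test_no_conflict_is_identity(self):
        props = self.frame([(0, 0, 0.1, 0.0), (1, 1, 0.2, 0.0)])
        pd.testing.assert_frame_equal(resolve_conflicts(props), props)

    def test_min_delta_t_wins(self):
        props = self.frame([(0, 0, 0.1, 0.5), (1, 0, 0.4, 0.0)])
        kept = resolve_conflicts(props)
        assert kept.red_idx.tolist() == [0]

    def test_tie_broken_by_least_transit_time_change(self):
        props = self.frame([(0, 0, 0.3, 0.30), (1, 0, 0.3, 0.02)])
        kept = resolve_conflicts(props)
        assert kept.red_idx.tolist() == [1]

    def test_loser_rematches_next_best(self):
        props = self.frame([(0, 0, 0.1, 0.0), (1, 0, 0.2, 0.0), (1, 1, 0.8, 0.0)])
        kept = resolve_conflicts(props)
        assert set(zip(kept.red_idx, kept.blue_idx)) == {(0, 0), (1, 1)}


class TestScorrColocalize:
    def test_error_free_simulation_fully_matched(self, geom):
        config = SimulationConfig(arrival_rate=100.0, duration=20.0, pt_error_cv=0.0, seed=13)
        gt = simulate_particles(config)
        red, blue = peak_tables(gt)
        for w in (0.5, 2.0):
            ms = scorr_colocalize(red, blue, geom, ScorrParams(w1=w, w2=w))
            assert ms.n_matches == len(gt)
            assert np.all(ms.matches.delta_t_ms < 1e-9)
            assert (ms.matches.red_true_id == ms.matches.blue_true_id).all()

    def test_missing_transit_time_column_is_instructive(self, geom):
        red = make_peaks([1.0], [0.5]).drop(columns="pt_ms")
        blue = make_peaks([6.0], [0.5], channel="blue")
        with pytest.raises(ValueError, match="detect_peaks"):
            scorr_colocalize(red, blue, geom)

    def test_agrees_with_naive_reference_on_random_instances(self, geom):
        rng = np.random.default_rng(17)
        for _ in range(30):
            nr, nb = rng.integers(1, 9, 2)
            red = make_peaks(np.sort(rng.uniform(0, 40, nr)), rng.uniform(0.34, 2.0, nr))
            blue = make_peaks(np.sort(rng.uniform(0, 60, nb)), rng.uniform(0.34, 2.0, nb), channel="blue")
            ms = scorr_colocalize(red, blue, geom, ScorrParams(w1=3.0, w2=2.0))
            got = set(zip(ms.matches.red_idx, ms.matches.blue_idx))
            assert got == naive_scorr(red, blue, geom, 3.0, 2.0)

    def test_match_count_monotone_in_w2(self, geom):
        config = SimulationConfig(arrival_rate=252.0, duration=10.0, seed=19)
        red, blue = peak_tables(simulate_particles(config))
        counts = [
            scorr_colocalize(red, blue, geom, ScorrParams(w1=5.0, w2=w2)).n_matches
            for w2 in (0.25, 0.5, 1.0, 2.0, 4.0)
        ]
        assert counts == sorted(counts)

    def test_permutation_invariance(self, geom):
        rng = np.random.default_rng(23)
        red = make_peaks(np.sort(rng.uniform(0, 200, 40)), rng.uniform(0.34, 2.0, 40))
        blue = make_peaks(np.sort(rng.uniform(0, 220, 40)), rng.uniform(0.34, 2.0, 40), channel="blue")
        ms_a = scorr_colocalize(red, blue, geom, ScorrParams(w1=3.0, w2=2.0))
        shuffled_red = red.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled_blue = blue.sample(frac=1.0, random_state=2).reset_index(drop=True)
        ms_b = scorr_colocalize(shuffled_red, shuffled_blue, geom, ScorrParams(w1=3.0, w2=2.0))
        pd.testing.assert_frame_equal(ms_a.matches, ms_b.matches)

    def test_order_swap_solved_by_transit_time_not_by_global_lag(self, geom):
        # particle A (slow, v=1) enters first; particle B (fast, v=3)
        # enters second and overtakes A between the lasers
        red = make_peaks([100.0, 101.0], [1.0, 1.0 / 3.0], ids=[0, 1])
        blue = make_peaks([106.0, 115.0], [1.0 / 3.0, 1.0], channel="blue", ids=[1, 0])
        ms = scorr_colocalize(red, blue, geom, ScorrParams(w1=2.0, w2=2.0))
        assert ms.n_matches == 2
        assert (ms.matches.red_true_id == ms.matches.blue_true_id).all()
        # the global-lag baseline must get at least one of them wrong
        k = find_lag(
            peaks_to_trace(red, 10_000.0, 140.0),
            peaks_to_trace(blue, 10_000.0, 140.0),
            20.0,
        )
        mx = xcorr_colocalize(red, blue, k, window_ms=4.5)
        wrong = (mx.matches.red_true_id != mx.matches.blue_true_id).sum()
        assert wrong + (2 - mx.n_matches) >= 1

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_matching_one_to_one_and_window_bounded(self, data):
        geom = LaserGeometry(dx1=1.0, dx2=1.0, dx3=15.0)
        n_red = data.draw(st.integers(0, 12))
        n_blue = data.draw(st.integers(0, 12))
        times_r = data.draw(
            st.lists(st.floats(0, 100), min_size=n_red, max_size=n_red)
        )
        times_b = data.draw(
            st.lists(st.floats(0, 120), min_size=n_blue, max_size=n_blue)
        )
        pts_r = data.draw(st.lists(st.floats(0.3, 3.0), min_size=n_red, max_size=n_red))
        pts_b = data.draw(st.lists(st.floats(0.3, 3.0), min_size=n_blue, max_size=n_blue))
        red = make_peaks(times_r, pts_r)
        blue = make_peaks(times_b, pts_b, channel="blue")
        w2 = data.draw(st.floats(0.1, 5.0))
        ms = scorr_colocalize(red, blue, geom, ScorrParams(w1=4.0, w2=w2))
        assert ms.matches.red_idx.is_unique
        assert ms.matches.blue_idx.is_unique
        assert (ms.matches.delta_t_ms <= w2).all()
        assert ms.n_matches + len(ms.unmatched_red) == len(red)
        assert ms.n_matches + len(ms.unmatched_blue) == len(blue)
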