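"""Straightness index, segment classification, chemokinesis."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from capitax import (
    AssayGeometry,
    Track,
    classify_segments,
    compare_straightness,
    instantaneous_speed,
    make_corona,
    segment_straightness,
    speed_vs_distance,
    straightness,
    straightness_robustness,
)
from capitax.behaviour import Segment, smooth_positions, truncate_to_arclength

try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False


def track_from_positions(pos, frame_rate=30.0, track_id=0):
    pos = np.asarray(pos, float)
    frames = np.arange(len(pos))
    return Track(track_id, frames, pos, frames / frame_rate)


class TestInstantaneousSpeed:
    def test_uniform_motion(self):
        pos = np.column_stack([5.0 * np.arange(30), np.zeros(30)])
        tr = track_from_positions(pos)
        v = instantaneous_speed(tr)
        assert np.allclose(v, 150.0)

    def test_stationary_cell(self):
        tr = track_from_positions(np.tile([3.0, 4.0], (20, 1)))
        assert np.allclose(instantaneous_speed(tr), 0.0)

    def test_matches_finite_difference_oracle(self):
        t = np.arange(60) / 30.0
        pos = np.column_stack([100 * np.sin(2 * np.pi * t), 50 * np.cos(2 * np.pi * t)])
        tr = track_from_positions(pos)
        v = instantaneous_speed(tr, smoothing_window=3)
        sm = smooth_positions(pos, 3)
        expected = np.linalg.norm(np.diff(sm, axis=0), axis=1) * 30.0
        assert np.allclose(v, expected)


class TestStraightness:
    def test_straight_segment_is_one(self):
        pos = np.column_stack([np.linspace(0, 100, 50), np.linspace(0, 40, 50)])
        assert straightness(pos) == pytest.approx(1.0)

    def test_closed_loop_is_zero(self):
        th = np.linspace(0, 2 * np.pi, 100)
        pos = np.column_stack([np.cos(th), np.sin(th)])
        assert straightness(pos) == pytest.approx(0.0, abs=1e-12)

    def test_semicircle_is_two_over_pi(self):
        th = np.linspace(0, np.pi, 2000)
        pos = 50 * np.column_stack([np.cos(th), np.sin(th)])
        assert straightness(pos) == pytest.approx(2 / np.pi, rel=1e-5)

    def test_bounds_and_collinearity(self, rng):
        for _ in range(50):
            pos = np.cumsum(rng.normal(0, 5, size=(30, 2)), axis=0)
            s = straightness(pos)
            assert 0 <= s <= 1 + 1e-12

    def test_similarity_invariance(self, rng):
        pos = np.cumsum(rng.normal(0, 5, size=(40, 2)), axis=0)
        s0 = straightness(pos)
        th = 1.1
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        for tf in (
            lambda p: p + [37.0, -12.0],
            lambda p: p @ R.T,
            lambda p: 3.7 * p,
            lambda p: 0.2 * (p @ R.T) + [5.0, 5.0],
        ):
            assert straightness(tf(pos)) == pytest.approx(s0, rel=1e-12)

    if HAVE_HYPOTHESIS:

        @given(
            st.lists(
                st.tuples(
                    st.floats(-1e3, 1e3, allow_nan=False),
                    st.floats(-1e3, 1e3, allow_nan=False),
                ),
                min_size=3,
                max_size=25,
            )
        )
        @settings(max_examples=60, deadline=None, derandomize=True)
        def test_net_never_exceeds_gross(self, pts):
            pos = np.asarray(pts, float)
            L = np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1))
            if L == 0:
                return
            assert straightness(pos) <= 1 + 1e-9


class TestClassifySegments:
    corona = make_corona(130.0, 20.0, 7)  # 60-200 um

    def radial_track(self, r_start, r_stop, n=60, t_offset=70.0):
        rr = np.linspace(r_start, r_stop, n)
        pos = np.column_stack([-rr / np.sqrt(2), rr / np.sqrt(2)])
        frames = np.arange(n)
        return Track(0, frames, pos, t_offset + frames / 30.0)

    def test_straight_in_track_is_ingoing(self, plain_geometry):
        tr = self.radial_track(250.0, 20.0)
        segs = classify_segments([tr], plain_geometry, self.corona)
        labels = {s.label for s in segs}
        assert labels == {"ingoing"}

    def test_straight_out_track_is_outgoing(self, plain_geometry):
        tr = self.radial_track(20.0, 250.0)
        segs = classify_segments([tr], plain_geometry, self.corona)
        assert {s.label for s in segs} == {"outgoing"}

    def test_neutral_needs_early_time_and_distance(self, plain_geometry):
        rr = np.full(40, 600.0)
        pos = np.column_stack([-rr, np.linspace(-50, 50, 40)])
        frames = np.arange(40)
        early = Track(0, frames, pos, frames / 30.0)  # t < 60 s
        late = Track(1, frames, pos, 100.0 + frames / 30.0)
        segs = classify_segments([early, late], plain_geometry, self.corona)
        assert [s.label for s in segs] == ["neutral"]
        assert segs[0].parent_id == 0

    def test_matches_pointwise_predicate_oracle(self, plain_geometry, rng):
        """Labels agree with a brute-force classifier applying the same
        predicates point by point."""
        tracks = []
        for i in range(100):
            n = 90
            start = rng.uniform(-500, 500, 2)
            pos = start + np.cumsum(rng.normal(0, 8, size=(n, 2)), axis=0)
            frames = np.arange(n)
            tracks.append(Track(i, frames, pos, rng.uniform(0, 100) + frames / 30.0))
        segs = classify_segments([t for t in tracks], plain_geometry, self.corona)
        # oracle
        expected = []
        for tr in tracks:
            r = np.hypot(tr.positions[:, 0], tr.positions[:, 1])
            in_cor = (
                (r >= self.corona.corona_inner)
                & (r <= self.corona.corona_outer)
                & (r <= 200.0)
                & (tr.times > 60.0)
            )
            far = (r > 400.0) & (tr.times < 60.0)
            for mask, kind in ((in_cor, "dir"), (far, "neutral")):
                runs, cur = [], None
                for k, m in enumerate(mask):
                    if m and cur is None:
                        cur = k
                    elif not m and cur is not None:
                        runs.append((cur, k))
                        cur = None
                if cur is not None:
                    runs.append((cur, len(mask)))
                for lo, hi in runs:
                    if hi - lo < 3:
                        continue
                    if kind == "neutral":
                        expected.append((tr.track_id, lo, "neutral"))
                    else:
                        lab = "ingoing" if r[hi - 1] < r[lo] else "outgoing"
                        expected.append((tr.track_id, lo, lab))
        got = sorted((s.parent_id, s.label) for s in segs)
        assert got == sorted((tid, lab) for tid, lo, lab in expected)

    def test_corona_wider_than_patch_rejected(self, plain_geometry):
        wide = make_corona(200.0, 20.0, 18)
        with pytest.raises(ValueError):
            classify_segments([], plain_geometry, wide, patch_radius=200.0)


class TestRobustness:
    def test_ballistic_segments_stay_straight(self, rng):
        segs = []
        for i in range(30):
            ang = rng.uniform(0, 2 * np.pi)
            n = 80
            pos = np.outer(np.arange(n) * 4.0, [np.cos(ang), np.sin(ang)])
            segs.append(Segment(i, "neutral", pos, np.arange(n) / 30.0))
        table = straightness_robustness(segs, min_segments=20)
        assert np.all(table["median_S"] > 0.999)
        assert not table["flagged"].any()

    def test_random_walk_median_decreases_with_length(self, rng):
        segs = []
        for i in range(120):
            pos = np.cumsum(rng.normal(0, 4, size=(400, 2)), axis=0)
            segs.append(Segment(i, "neutral", pos, np.arange(400) / 30.0))
        table = straightness_robustness(segs, min_segments=20)
        med = table["median_S"].to_numpy()
        assert med[-1] < med[0]
        assert np.all(np.diff(med) < 0.05)  # decreasing up to MC jitter

    def test_truncation_at_full_length_is_identity(self):
        pos = np.column_stack([np.arange(50.0), np.zeros(50)])
        trunc = truncate_to_arclength(pos, 49.0)
        assert trunc is not None and len(trunc) == 50
        assert straightness(trunc) == straightness(pos)


class TestCompareStraightness:
    def test_identical_groups_all_one(self):
        g = {"a": np.array([0.5, 0.6, 0.7]), "b": np.array([0.5, 0.6, 0.7])}
        pvals = compare_straightness(g)
        assert all(p > 0.3 for p in pvals.values())

    def test_separated_groups_significant(self):
        g = {
            "hi": np.linspace(0.9, 1.0, 12),
            "lo": np.linspace(0.1, 0.2, 12),
        }
        pvals = compare_straightness(g)
        assert pvals[("hi", "lo")] < 0.01

    def test_matches_exact_permutation_oracle(self):
        a = np.array([0.91, 0.82, 0.95, 0.70])
        b = np.array([0.55, 0.48, 0.62])
        p_pkg = compare_straightness({"a": a, "b": b})[("a", "b")]
        pooled = np.concatenate([a, b])
        u_obs = sps.mannwhitneyu(a, b, alternative="two-sided").statistic
        n_a = len(a)
        count = total = 0
        for combo in itertools.combinations(range(7), n_a):
            ga = pooled[list(combo)]
            gb = pooled[[i for i in range(7) if i not in combo]]
            u = sps.mannwhitneyu(ga, gb, alternative="two-sided").statistic
            total += 1
            count += u >= u_obs - 1e-12
        p_exact = min(1.0, 2 * count / total)
        assert p_pkg == pytest.approx(p_exact, abs=0.05)


class TestSpeedVsDistance:
    def test_uniform_speed_ratio_one(self, plain_geometry, rng):
        tracks = []
        for i in range(20):
            ang = rng.uniform(0, 2 * np.pi)
            start = rng.uniform(-400, 400, 2)
            pos = start + np.outer(np.arange(60) * 4.0, [np.cos(ang), np.sin(ang)])
            tracks.append(track_from_positions(pos, track_id=i))
        prof = speed_vs_distance(tracks, plain_geometry, smoothing_window=1)
        assert prof.chemokinesis_ratio == pytest.approx(1.0, abs=0.02)

    def test_column_frequencies_sum_to_one(self, plain_geometry, rng):
        tracks = []
        for i in range(10):
            pos = np.cumsum(rng.normal(0, 6, size=(100, 2)), axis=0)
            tracks.append(track_from_positions(pos, track_id=i))
        prof = speed_vs_distance(tracks, plain_geometry)
        sums = prof.frequencies.sum(axis=0)
        populated = sums > 0
        assert np.allclose(sums[populated], 1.0)

    def test_simulated_chemokinesis_recovered(self, plain_geometry):
        """A kappa tuned for 1.5x near-source speed is recovered by the
        speed-versus-distance statistic within Monte-Carlo error."""
        from capitax import GradientModel, SwimmerConfig, simulate_assay

        # slow-diffusing, low-background field: inside 200 um the speed gain
        # saturates (sat ~ 0.9), beyond it sat ~ 0, so kappa = 0.55 puts the
        # near/far median-speed ratio at ~1.5
        swim = SwimmerConfig(
            n_cells=120, duration=120.0, dt=1 / 30.0, kappa=0.55, K_half=0.2,
            seed=21, arena_radius=600.0,
        )
        grad = GradientModel(D=100.0, C0=0.005)
        tracks = simulate_assay(swim, grad)
        # analyse the developed-gradient phase (t >= 60 s)
        late = []
        for tr in tracks:
            keep = tr.times >= 60.0
            late.append(Track(tr.track_id, tr.frames[keep], tr.positions[keep], tr.times[keep]))
        prof = speed_vs_distance(late, plain_geometry, near_radius=200.0)
        assert prof.chemokinesis_ratio == pytest.approx(1.5, abs=0.1)
        assert prof.p_value < 0.01
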