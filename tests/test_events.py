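"""Virtual-screen projection, screen fitting, and adaptive event detection."""

import numpy as np
import pytest

import gazeload as gz
from gazeload.events import (
    ScreenGaze,
    combined_gaze_ray,
    detect_fixations_saccades,
    fit_virtual_screen,
    project_to_plane,
)

Z = np.array([0.0, 0.0, 1.0])
Y = np.array([0.0, 1.0, 0.0])


class TestCombinedGazeRay:
    def test_direction_is_normalized_head_to_focus(self):
        d = combined_gaze_ray(np.zeros(3), np.array([0.0, 0.0, 2.0]))
        assert np.allclose(d, [0, 0, 1])

    def test_focus_at_head_is_invalid(self):
        assert combined_gaze_ray(np.zeros(3), np.array([0.0, 0.0, 1e-4])) is None

    def test_unit_norm_for_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            h = rng.normal(size=3)
            f = h + rng.normal(size=3)
            d = combined_gaze_ray(h, f)
            if d is not None:
                assert np.linalg.norm(d) == pytest.approx(1.0, abs=1e-9)


class TestProjectToPlane:
    def test_on_axis_gaze_maps_to_origin(self):
        pts, ok = project_to_plane(Z[None], Z[None], Y[None])
        assert ok[0]
        assert np.allclose(pts[0], [0.0, 0.0], atol=1e-12)

    def test_ten_degrees_right_matches_trigonometry(self):
        """x = 3 tan(10 deg) ~ 0.529 m on the 3 m plane."""
        a = np.radians(10.0)
        d = np.array([[np.sin(a), 0.0, np.cos(a)]])
        pts, ok = project_to_plane(d, Z[None], Y[None])
        assert ok[0]
        assert pts[0, 0] == pytest.approx(3.0 * np.tan(a), rel=1e-12)
        assert pts[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_head_space_invariance_under_rigid_rotation(self):
        """Rotating head and gaze together leaves plane coordinates unchanged."""
        rng = np.random.default_rng(1)
        a = np.radians(7.0)
        gaze_local = np.array([np.sin(a), 0.1, np.cos(a)])
        gaze_local /= np.linalg.norm(gaze_local)
        base, _ = project_to_plane(gaze_local[None], Z[None], Y[None])
        for _ in range(10):
            # random rotation via QR decomposition
            q, _r = np.linalg.qr(rng.normal(size=(3, 3)))
            if np.linalg.det(q) < 0:
                q[:, 0] *= -1
            pts, ok = project_to_plane(
                (q @ gaze_local)[None], (q @ Z)[None], (q @ Y)[None]
            )
            assert ok[0]
            assert np.allclose(pts[0], base[0], atol=1e-9)

    def test_gaze_beyond_89_degrees_invalid(self):
        a = np.radians(89.5)
        d = np.array([[np.sin(a), 0.0, np.cos(a)]])
        _, ok = project_to_plane(d, Z[None], Y[None])
        assert not ok[0]


class TestFitVirtualScreen:
    def test_one_inch_extent_spans_150_pixels(self):
        xs = np.linspace(-0.0127, 0.0127, 101)
        pts = np.column_stack([xs, xs])
        screen, gaze = fit_virtual_screen(pts, trim_quantile=0.0)
        assert screen.width_px == pytest.approx(150.0, rel=1e-9)
        assert gaze.x_px.min() == pytest.approx(0.0, abs=1e-9)
        assert gaze.x_px.max() == pytest.approx(150.0, rel=1e-9)

    def test_y_axis_flipped_to_screen_convention(self):
        pts = np.column_stack([np.linspace(-0.01, 0.01, 101), np.linspace(-0.01, 0.01, 101)])
        _, gaze = fit_virtual_screen(pts, trim_quantile=0.0)
        assert gaze.y_px[0] > gaze.y_px[-1]  # low plane-y is at the bottom

    def test_extreme_outliers_do_not_inflate_the_screen(self):
        """Bounds at the 0.0025 quantile ignore a couple of wild points."""
        rng = np.random.default_rng(2)
        pts = rng.uniform(-0.05, 0.05, size=(1000, 2))
        pts[0] = [5.0, 5.0]
        pts[1] = [-5.0, -5.0]
        screen, _ = fit_virtual_screen(pts)
        centered = pts - np.median(pts, axis=0)
        lo = np.quantile(centered, 0.0025, axis=0)
        hi = np.quantile(centered, 0.9975, axis=0)
        assert screen.width_m == pytest.approx(hi[0] - lo[0], rel=1e-9)
        assert screen.width_m < 0.2

    def test_symmetric_cloud_is_median_centered(self):
        xs = np.linspace(-0.03, 0.03, 201)
        pts = np.column_stack([xs, np.zeros_like(xs)])
        pts = np.vstack([pts, np.column_stack([np.zeros(11), np.linspace(-0.01, 0.01, 11)])])
        screen, _ = fit_virtual_screen(pts, trim_quantile=0.0)
        assert screen.x_min_m == pytest.approx(-0.03, abs=1e-9)

    def test_degenerate_spread_is_an_error(self):
        pts = np.tile([0.1, 0.2], (50, 1))
        with pytest.raises(ValueError):
            fit_virtual_screen(pts)

    def test_too_few_points_is_an_error(self):
        with pytest.raises(ValueError):
            fit_virtual_screen(np.random.default_rng(0).normal(size=(5, 2)))


def _gaze(x, y, t, valid=None):
    x = np.asarray(x, float)
    valid = np.ones(len(x), bool) if valid is None else np.asarray(valid, bool)
    return ScreenGaze(time=np.asarray(t, float), x_px=x, y_px=np.asarray(y, float),
                      valid=valid)


class TestDetectFixationsSaccades:
    def test_still_gaze_yields_single_fixation(self):
        n = 3600  # 40 s at 90 Hz
        t = np.arange(n) / 90.0
        events = detect_fixations_saccades(_gaze(np.full(n, 100.0), np.full(n, 50.0), t))
        assert len(events) == 1
        assert events[0].kind == "fixation"
        assert events[0].start_index == 0
        assert events[0].end_index == n - 1

    def test_two_fixations_and_one_jump(self):
        """A high-velocity jump splits the trace into 2 fixations, 1 saccade
        with boundaries within one sample of construction."""
        t = np.arange(200) / 90.0
        x = np.zeros(200)
        jump = np.linspace(0.0, 500.0, 7)  # 6 moving intervals, ~67 ms
        x[90:97] = jump
        x[97:] = 500.0
        events = detect_fixations_saccades(_gaze(x, np.zeros(200), t))
        kinds = [e.kind for e in events]
        assert kinds == ["fixation", "saccade", "fixation"]
        sac = events[1]
        assert abs(sac.start_index - 90) <= 1
        assert abs(sac.end_index - 96) <= 1

    def test_blink_gap_breaks_events(self):
        t = np.arange(400) / 90.0
        valid = np.ones(400, bool)
        valid[200:220] = False
        events = detect_fixations_saccades(
            _gaze(np.zeros(400), np.zeros(400), t, valid)
        )
        assert [e.kind for e in events] == ["fixation", "fixation"]
        assert events[0].end_index < 200
        assert events[1].start_index >= 220

    def test_short_valid_span_is_an_error(self):
        t = np.arange(30) / 90.0
        with pytest.raises(ValueError):
            detect_fixations_saccades(_gaze(np.zeros(30), np.zeros(30), t))

    def test_sub_minimum_fixation_dropped(self):
        """A sub-threshold run shorter than the minimum fixation is no event."""
        t = np.arange(300) / 90.0
        x = np.zeros(300)
        x[150:156] = np.linspace(0, 400, 6)
        x[156:160] = 400.0  # 4 samples ~44 ms < 100 ms
        x[160:166] = np.linspace(400, 800, 6)
        x[166:] = 800.0
        events = detect_fixations_saccades(_gaze(x, np.zeros(300), t))
        fix_spans = [(e.start_index, e.end_index) for e in events if e.kind == "fixation"]
        assert not any(s <= 157 <= e for s, e in fix_spans)

    def test_events_disjoint_and_ordered(self, sim_trial):
        trial, _ = sim_trial
        p = gz.process_trial(trial)
        gaze_events = [e for e in p.events if e.kind != "blink"]
        for a, b in zip(gaze_events, gaze_events[1:]):
            assert a.end_index < b.start_index
            assert a.end_time <= b.start_time

    def test_uniform_rate_compatibility_mode(self):
        t = np.arange(400) / 90.0
        g = _gaze(np.zeros(400), np.zeros(400), t)
        native = detect_fixations_saccades(g)
        compat = detect_fixations_saccades(g, assume_uniform_rate=True)
        assert [e.kind for e in native] == [e.kind for e in compat]


def test_fixation_rate_multiplier_orders_detected_counts(default_config):
    """Cohort fixation counts follow the configured rate multipliers."""
    counts = {}
    for cond in gz.CONDITIONS:
        per_section = []
        for seed in (31, 32, 33):
            trial, _ = gz.simulate_trial(default_config, cond, "P01", seed)
            p = gz.process_trial(trial)
            agg = gz.trial_aggregates(p)
            per_section += agg["fixation_count"].tolist()
        counts[cond] = np.mean(per_section)
    mult = default_config.fixation_rate_multiplier
    order_by_mult = sorted(gz.CONDITIONS, key=lambda c: mult[c])
    order_by_count = sorted(gz.CONDITIONS, key=lambda c: counts[c])
    assert order_by_mult[0] == "EN-Familiar"
    assert order_by_count[0] == "EN-Familiar"
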