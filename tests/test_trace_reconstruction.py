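import numpy as np
import pytest
from hypothesis import given, strategies as st

import eyescript as es
from eyescript.preprocessing import BipolarSignal
from eyescript.saccade_detection import SaccadeMask
from eyescript.trace_reconstruction import EyeTrace


def trace_of(points, normalized=False):
    return EyeTrace(np.asarray(points, dtype=float), normalized=normalized)


class TestExtractTrace:
    def _sig(self, n=20):
        h = np.arange(float(n))
        v = -np.arange(float(n))
        return BipolarSignal(h, v, 64.0)

    def test_all_true_mask_keeps_everything(self):
        sig = self._sig()
        mask = SaccadeMask(np.ones(20, dtype=bool), [(0, 19)], 120.0)
        out = es.extract_trace(sig, mask)
        np.testing.assert_allclose(out.x, sig.h)
        np.testing.assert_allclose(out.y, sig.v)

    def test_two_segments_concatenate_in_order(self):
        sig = self._sig()
        mask = SaccadeMask(None, [(2, 6), (10, 14)], 120.0)
        mask.mask = np.zeros(20, dtype=bool)
        for s, e in mask.segments:
            mask.mask[s:e + 1] = True
        out = es.extract_trace(sig, mask)
        assert len(out) == 10
        np.testing.assert_allclose(out.x, np.r_[2:7, 10:15].astype(float))

    def test_empty_mask_is_degenerate(self):
        sig = self._sig()
        mask = SaccadeMask(np.zeros(20, dtype=bool), [], 120.0)
        with pytest.raises(es.DegenerateTraceError):
            es.extract_trace(sig, mask)

    def test_two_stroke_digit_yields_one_corner(self, templates):
        # digit 1 = flag + descender: two detected strokes whose net
        # displacement vectors meet at the template's corner angle
        assert templates[1].n_strokes == 2
        ep = es.simulate_epoch(templates[1], es.clean_config(), seed=1)
        _, st = es.reconstruct(ep.recording, return_stages=True)
        segments = st["detect_saccades"].segments
        assert len(segments) == 2
        sig = st["remove_drift"]
        strokes = []
        for s, e in segments:
            strokes.append([sig.h[e] - sig.h[s], sig.v[e] - sig.v[s]])
        u = np.asarray(strokes)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        corner = np.degrees(np.arccos(np.clip(u[0] @ u[1], -1, 1)))
        wp = templates[1].waypoints
        winc = np.diff(wp, axis=0).astype(float)
        winc /= np.linalg.norm(winc, axis=1, keepdims=True)
        expected = np.degrees(np.arccos(np.clip(winc[0] @ winc[1], -1, 1)))
        assert corner == pytest.approx(expected, abs=15)


class TestResampleEquidistant:
    def test_straight_segment_uniformly_subdivided(self):
        out = es.resample_equidistant(trace_of([(0, 0), (1, 0)]), 5)
        np.testing.assert_allclose(out.x, [0, 0.25, 0.5, 0.75, 1.0], atol=1e-9)
        np.testing.assert_allclose(out.y, 0.0, atol=1e-12)

    def test_l_shape_gaps_all_equal(self):
        out = es.resample_equidistant(trace_of([(0, 0), (1, 0), (1, 1)]), 5)
        gaps = np.hypot(*np.diff(out.points, axis=0).T)
        np.testing.assert_allclose(gaps, 0.5, rtol=1e-6)
        np.testing.assert_allclose(out.points[0], (0, 0))
        np.testing.assert_allclose(out.points[-1], (1, 1))

    def test_gaps_equal_except_corner_straddles(self, rng):
        for _ in range(5):
            pts = np.cumsum(rng.normal(size=(6, 2)), axis=0)
            out = es.resample_equidistant(trace_of(pts), 64)
            gaps = np.hypot(*np.diff(out.points, axis=0).T)
            g = np.median(gaps)
            # a gap can only deviate by cutting a corner, so: never longer,
            # and no more short gaps than the polyline has corners
            assert gaps.max() <= g * (1 + 1e-6)
            assert (gaps < g * (1 - 1e-6)).sum() <= len(pts) - 2

    def test_idempotent_on_equidistant_trace(self):
        first = es.resample_equidistant(trace_of([(0, 0), (2, 0), (2, 2)]), 9)
        again = es.resample_equidistant(first, 9)
        np.testing.assert_allclose(again.points, first.points, atol=1e-9)

    def test_total_length_preserved(self, templates):
        # chords cut corners, so the loss is bounded by one gap per corner
        # (a hairpin can cost a full gap); corner-light shapes stay within
        # 1 %, corner-dense digit patterns within 2 % at n = 128
        for tpl in templates:
            out = es.resample_equidistant(trace_of(tpl.waypoints), 128)
            before = np.hypot(*np.diff(tpl.waypoints, axis=0).T).sum()
            after = np.hypot(*np.diff(out.points, axis=0).T).sum()
            gap = before / 127
            n_corners = len(tpl.waypoints) - 2
            assert before - after <= (n_corners + 1) * gap
            assert after == pytest.approx(before, rel=0.02)
        straight = es.resample_equidistant(
            trace_of([(0, 0), (3, 0), (3, 4)]), 128)
        after = np.hypot(*np.diff(straight.points, axis=0).T).sum()
        assert after == pytest.approx(7.0, rel=0.01)

    def test_degenerate_path_rejected(self):
        with pytest.raises(es.DegenerateTraceError):
            es.resample_equidistant(trace_of([(1, 1), (1, 1)]), 8)
        with pytest.raises(es.ArgumentError):
            es.resample_equidistant(trace_of([(0, 0), (1, 1)]), 1)


class TestNormalizeBox:
    def test_spans_unit_box(self):
        out = es.normalize_box(trace_of([(2, 10), (4, 20), (3, 15)]))
        assert out.x.min() == 0 and out.x.max() == 1
        assert out.y.min() == 0 and out.y.max() == 1
        assert out.normalized

    def test_aspect_ratio_not_preserved(self):
        out = es.normalize_box(trace_of([(0, 0), (10, 1)]))
        np.testing.assert_allclose(out.points, [(0, 0), (1, 1)])

    @given(st.floats(0.1, 50), st.floats(-100, 100), st.floats(-100, 100))
    def test_translation_scale_invariant(self, a, bx, by):
        pts = np.array([(0.0, 0), (1, 2), (3, 1), (2, 2)])
        base = es.normalize_box(trace_of(pts))
        moved = es.normalize_box(trace_of(a * pts + np.array([bx, by])))
        np.testing.assert_allclose(moved.points, base.points, atol=1e-9)

    def test_idempotent(self):
        once = es.normalize_box(trace_of([(0, 0), (1, 2), (3, 1)]))
        twice = es.normalize_box(once)
        np.testing.assert_allclose(twice.points, once.points, atol=1e-12)

    def test_degenerate_axis_centred(self):
        out = es.normalize_box(trace_of([(5, 0), (5, 1), (5, 2)]))
        np.testing.assert_allclose(out.x, 0.5)
        np.testing.assert_allclose(out.y, [0, 0.5, 1.0])


class TestFiniteDifference:
    def test_central_difference_of_ramp(self):
        np.testing.assert_allclose(es.finite_difference([0, 1, 2, 3]), [2, 2])

    def test_constant_gives_zeros(self):
        np.testing.assert_allclose(es.finite_difference(np.full(10, 3.0)), 0.0)

    def test_matches_loop_oracle(self, rng):
        s = rng.normal(size=50)
        oracle = np.array([s[t + 1] - s[t - 1] for t in range(1, 49)])
        np.testing.assert_allclose(es.finite_difference(s), oracle)

    def test_short_input_rejected(self):
        with pytest.raises(es.ArgumentError):
            es.finite_difference([1.0, 2.0])


class TestCrosstalk:
    def test_identity_trace_forces_alpha_one(self):
        t = np.linspace(0, 1, 50)
        pts = np.column_stack([np.sin(3 * t) * 0.5 + t, np.sin(3 * t) * 0.5 + t])
        model = es.estimate_alpha(trace_of(pts, normalized=True))
        assert model.alpha == pytest.approx(1.0)

    def test_independent_symmetric_strokes_give_alpha_zero(self, ttraces):
        # closed rectilinear shapes: vertical and horizontal increments
        # are orthogonal, so no spurious interdependency is seen
        for digit in (0, 8):
            assert abs(es.estimate_alpha(ttraces[digit]).alpha) < 0.02

    def test_injected_alpha_recovered(self, rng, ttraces):
        for a0 in (-0.3, 0.3):
            pts = ttraces[0].points.copy()
            pts[:, 1] += a0 * pts[:, 0]
            pts += rng.normal(0, 0.01, pts.shape)
            model = es.estimate_alpha(trace_of(pts, normalized=True))
            assert model.alpha == pytest.approx(a0, abs=0.05)
            assert abs(model.fit_slope_after) < 1e-6

    def test_zero_variance_x_rejected(self):
        pts = np.column_stack([np.full(10, 0.5), np.linspace(0, 1, 10)])
        with pytest.raises(es.EstimationError):
            es.estimate_alpha(trace_of(pts, normalized=True))

    def test_remove_with_alpha_zero_is_identity(self, ttraces):
        model = es.CrosstalkModel(0.0, 0.0, 0.0)
        out = es.remove_crosstalk(ttraces[3], model, renormalize=False)
        np.testing.assert_allclose(out.points, ttraces[3].points)

    def test_alpha_one_flattens_identity_trace(self):
        t = np.linspace(0, 1, 20)
        pts = np.column_stack([t, t])
        out = es.remove_crosstalk(trace_of(pts, normalized=True),
                                  es.CrosstalkModel(1.0, 1.0, 0.0),
                                  renormalize=False)
        np.testing.assert_allclose(out.y, 0.0, atol=1e-12)

    def test_compensation_is_a_fixed_point(self, rng, ttraces):
        pts = ttraces[5].points.copy()
        pts[:, 1] += 0.25 * pts[:, 0]
        pts += rng.normal(0, 0.005, pts.shape)
        first = trace_of(pts, normalized=True)
        model = es.estimate_alpha(first)
        comp = es.remove_crosstalk(first, model)
        assert abs(es.estimate_alpha(comp).alpha) < 0.02


class TestReconstructPipeline:
    @staticmethod
    def _mean_dist_to_template(trace, tpl):
        wp = tpl.waypoints.astype(float)
        rng_ = wp.max(0) - wp.min(0)
        wp = (wp - wp.min(0)) / np.where(rng_ > 0, rng_, 1.0)
        d = np.full(len(trace.points), np.inf)
        for a, b in zip(wp[:-1], wp[1:]):
            ab = b - a
            tt = np.clip(((trace.points - a) @ ab) / (ab @ ab), 0, 1)
            proj = a + tt[:, None] * ab
            d = np.minimum(d, np.hypot(*(trace.points - proj).T))
        return d.mean()

    def test_noiseless_digit_trace_close_to_template(self, templates,
                                                     clean_epochs):
        # balanced closed shapes reconstruct almost exactly; digits whose
        # gaze staircase trends monotonically pick up a bounded shear from
        # the epoch-wide linear detrending (worst: '4', trending on both
        # axes) yet remain well inside their own template's basin
        for digit in (0, 8):
            _, trace = clean_epochs[digit]
            assert self._mean_dist_to_template(trace, templates[digit]) < 0.05
        for digit in range(10):
            _, trace = clean_epochs[digit]
            assert self._mean_dist_to_template(trace, templates[digit]) < 0.3

    def test_no_saccadic_content_fails_in_extract_stage(self):
        rec = es.EogRecording(np.random.default_rng(0).normal(0, 1, (8192, 4)),
                              2048.0,
                              {"left": 0, "right": 1, "above": 2, "below": 3})
        with pytest.raises(es.PipelineStageError) as err:
            es.reconstruct(rec)
        assert err.value.stage == "extract_trace"

    def test_deterministic(self, templates):
        ep = es.simulate_epoch(templates[6], es.SynthConfig(), seed=9)
        t1 = es.reconstruct(ep.recording)
        t2 = es.reconstruct(ep.recording)
        np.testing.assert_array_equal(t1.points, t2.points)

    def test_epoch_alpha_recovered_in_normalized_units(self, templates):
        # the pipeline estimates alpha after per-axis normalization, so the
        # recoverable quantity is alpha scaled by the axis-extent ratio;
        # closed balanced digits satisfy the estimator's independence
        # assumption, so injecting crosstalk shifts the estimate by exactly
        # that scaled amount
        for digit in (0, 8):
            alphas = {}
            for a0 in (0.0, 0.3):
                ep = es.simulate_epoch(templates[digit],
                                       es.clean_config(alpha=a0), seed=2)
                _, st = es.reconstruct(ep.recording, return_stages=True)
                alphas[a0] = st["estimate_alpha"].alpha
            gx, gy = ep.truth.gaze_x, ep.truth.gaze_y
            sx = gx.max() - gx.min()
            v = gy + 0.3 * gx
            sy = v.max() - v.min()
            assert abs(alphas[0.0]) < 0.02
            assert alphas[0.3] - alphas[0.0] == pytest.approx(0.3 * sx / sy,
                                                              abs=0.05)

    def test_compensated_shape_beats_uncompensated(self, templates, ttraces):
        # with injected crosstalk, compensation must bring the trace closer
        # to its template under DTW
        cfg = es.clean_config(alpha=0.35)
        ep = es.simulate_epoch(templates[0], cfg, seed=4)
        with_c = es.reconstruct(ep.recording)
        from dataclasses import replace
        no_c = es.reconstruct(ep.recording,
                              replace(es.PipelineConfig(),
                                      compensate_crosstalk=False))
        d_with = es.dtw_dissimilarity(with_c, ttraces[0]).d
        d_without = es.dtw_dissimilarity(no_c, ttraces[0]).d
        assert d_with < d_without
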