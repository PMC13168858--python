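import numpy as np
import pytest

from ocumet import metrics as om
from ocumet.segeval import FrameMasks
from ocumet.synthetic import TraceParams, render_frames_and_masks, simulate_binocular, simulate_trace
from ocumet.trace import OcularTrace


def make_trace(
    fissure,
    diameter=None,
    x=None,
    y=None,
    valid=None,
    frame_rate=30.0,
):
    fissure = np.asarray(fissure, dtype=float)
    n = len(fissure)
    diameter = np.full(n, 20.0) if diameter is None else np.asarray(diameter, float)
    x = np.full(n, 100.0) if x is None else np.asarray(x, float)
    y = np.full(n, 50.0) if y is None else np.asarray(y, float)
    valid = np.ones(n, bool) if valid is None else np.asarray(valid, bool)
    diameter = np.where(valid, diameter, np.nan)
    return OcularTrace(
        eye="left",
        frame_rate=frame_rate,
        fissure_length=fissure,
        pupil_diameter=diameter,
        pupil_x=np.where(valid, x, np.nan),
        pupil_y=np.where(valid, y, np.nan),
        valid=valid,
    )


class TestTraceFromMasks:
    def test_empty_pupil_mask_invalid(self):
        shape = (40, 40)
        stack = [
            FrameMasks(0, {("palpebral_fissure", "left"): np.ones(shape, bool)}),
        ]
        t = om.trace_from_masks(stack, 30.0)
        assert not t.valid[0]

    def test_circular_pupil_diameter(self):
        yy, xx = np.mgrid[0:60, 0:60]
        disk = (yy - 30) ** 2 + (xx - 30) ** 2 <= 10**2
        stack = [FrameMasks(0, {("pupil", "left"): disk})]
        t = om.trace_from_masks(stack, 30.0)
        assert t.pupil_diameter[0] == pytest.approx(20.0, rel=0.02)
        assert t.pupil_x[0] == pytest.approx(30.0, abs=0.5)

    def test_fissure_length_matches_generator(self):
        src = simulate_trace(TraceParams(n_frames=30, rng_seed=2))
        _, masks = render_frames_and_masks(src)
        t = om.trace_from_masks(masks, 30.0)
        open_frames = src.fissure_length >= 2.0
        assert np.all(
            np.abs(t.fissure_length[open_frames] - src.fissure_length[open_frames]) <= 2.0
        )

    def test_empty_stack_raises(self):
        with pytest.raises(ValueError):
            om.trace_from_masks([], 30.0)


class TestDetectBlinks:
    def test_constant_open_trace(self):
        assert om.detect_blinks(make_trace(np.full(100, 30.0))) == []

    def test_single_injected_closure_duration(self):
        f = np.full(100, 30.0)
        f[50:55] = 1.0  # 5-frame closure
        events = om.detect_blinks(make_trace(f))
        assert len(events) == 1
        assert events[0].duration == pytest.approx(5 * 1000 / 30)

    def test_simulated_blinks_recovered_exactly(self, clean_trace):
        events = om.detect_blinks(clean_trace)
        assert len(events) == len(clean_trace.truth.blinks)
        for ev, (s, e) in zip(events, clean_trace.truth.blinks):
            assert (ev.start_frame, ev.end_frame) == (s, e)

    def test_flat_zero_trace_warns(self):
        t = make_trace(np.zeros(50), valid=np.zeros(50, bool))
        with pytest.warns(UserWarning):
            assert om.detect_blinks(t) == []

    def test_single_frame_dips_rejected(self):
        f = np.full(100, 30.0)
        f[10] = 0.0
        assert om.detect_blinks(make_trace(f)) == []


class TestBlinkMetrics:
    def test_no_events(self):
        rate, dur, interval = om.blink_metrics([], 60.0)
        assert rate == 0
        assert np.isnan(dur) and np.isnan(interval)

    def test_rate_definitional(self):
        events = [om.BlinkEvent(i * 60, i * 60 + 3, 100.0) for i in range(20)]
        rate, _, _ = om.blink_metrics(events, 60.0)
        assert rate == pytest.approx(20.0)

    def test_interval_offset_to_onset(self):
        events = [
            om.BlinkEvent.from_bounds(100, 200, 30.0),
            om.BlinkEvent.from_bounds(260, 300, 30.0),
        ]
        _, _, interval = om.blink_metrics(events, 60.0, frame_rate=30.0)
        assert interval == pytest.approx((260 - 200) * 1000 / 30)  # 2000 ms

    def test_bad_duration_raises(self):
        with pytest.raises(ValueError):
            om.blink_metrics([], 0.0)


class TestPerclos:
    def test_always_open(self):
        assert om.perclos(make_trace(np.full(100, 30.0))) == 0.0

    def test_always_closed(self):
        t = make_trace(np.zeros(100), valid=np.zeros(100, bool))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert om.perclos(t) == 100.0

    def test_300_of_1600(self):
        f = np.full(1600, 30.0)
        f[100:400] = 1.0
        assert om.perclos(make_trace(f)) == pytest.approx(18.75)

    def test_perclos_at_least_blink_frame_fraction(self, clean_trace):
        events = om.detect_blinks(clean_trace)
        blink_frames = sum(e.end_frame - e.start_frame + 1 for e in events)
        assert om.perclos(clean_trace) >= 100.0 * blink_frames / clean_trace.n_frames - 1e-9


class TestDetectFixations:
    def test_constant_centroid_single_fixation(self):
        t = make_trace(np.full(1800, 30.0))
        events = om.detect_fixations(t)
        assert len(events) == 1
        assert events[0].duration == pytest.approx(60_000.0)

    def test_alternating_centroid_no_fixations(self):
        n = 200
        x = np.where(np.arange(n) % 2 == 0, 0.0, 100.0)
        t = make_trace(np.full(n, 30.0), x=x)
        assert om.detect_fixations(t) == []

    def test_generator_plateaus_recovered(self, clean_trace):
        events = om.detect_fixations(clean_trace)
        assert len(events) == len(clean_trace.truth.fixations)

    def test_invalid_frames_split_fixations(self):
        valid = np.ones(300, bool)
        valid[150:160] = False
        t = make_trace(np.full(300, 30.0), valid=valid)
        assert len(om.detect_fixations(t)) == 2


class TestMovementDistance:
    def test_three_four_five(self):
        t = make_trace(np.full(2, 30.0), x=[0, 3], y=[0, 4])
        assert om.movement_distance(t) == pytest.approx(5.0)

    def test_constant_centroid(self):
        assert om.movement_distance(make_trace(np.full(50, 30.0))) == 0.0

    def test_gap_pairs_excluded(self):
        valid = np.array([True, True, False, True])
        t = make_trace(np.full(4, 30.0), x=[0, 1, 3, 5], y=[0, 0, 0, 0], valid=valid)
        assert om.movement_distance(t) == pytest.approx(1.0)

    def test_too_few_valid_warns(self):
        t = make_trace(np.full(5, 30.0), valid=[True, False, False, False, False])
        with pytest.warns(UserWarning):
            assert om.movement_distance(t) == 0.0


class TestConstrictionSpeeds:
    def test_constant_diameter(self):
        t = make_trace(np.full(50, 30.0), diameter=np.full(50, 20.0))
        assert om.constriction_speeds(t) == (0.0, 0.0)

    def test_one_pixel_drop_at_30fps(self):
        t = make_trace(np.full(2, 30.0), diameter=[20.0, 19.0])
        max_s, avg_s = om.constriction_speeds(t)
        assert max_s == pytest.approx(30.0)
        assert avg_s == pytest.approx(30.0)

    def test_dilating_trace(self):
        t = make_trace(np.full(10, 30.0), diameter=np.linspace(18, 22, 10))
        assert om.constriction_speeds(t) == (0.0, 0.0)


class TestWindowedVariability:
    def test_constant_signal(self):
        t = make_trace(np.full(700, 30.0))
        sd, var, cv = om.windowed_variability(t, om.WindowSpec.named("early"), "fissure_length")
        assert (sd, var, cv) == (0.0, 0.0, 0.0)

    def test_hand_computed_samples(self):
        f = np.full(600, 30.0)
        t = make_trace(f, diameter=np.r_[np.full(200, 5.0), np.tile([2.0, 4.0, 6.0], 134)[:400]])
        spec = om.WindowSpec("w", 200, 203)
        sd, var, cv = om.windowed_variability(t, spec, "pupil_size")
        assert sd == pytest.approx(2.0)
        assert var == pytest.approx(4.0)
        assert cv == pytest.approx(50.0)

    def test_variance_is_sd_squared(self, rng):
        d = rng.uniform(15, 25, 1800)
        t = make_trace(np.full(1800, 30.0), diameter=d)
        for win in om.WINDOWS:
            sd, var, _ = om.windowed_variability(t, om.WindowSpec.named(win), "pupil_size")
            assert var == pytest.approx(sd**2)

    def test_cv_scale_invariance(self, rng):
        d = rng.uniform(15, 25, 700)
        t1 = make_trace(np.full(700, 30.0), diameter=d)
        t2 = make_trace(np.full(700, 30.0), diameter=3.5 * d)
        spec = om.WindowSpec.named("early")
        sd1, var1, cv1 = om.windowed_variability(t1, spec, "pupil_size")
        sd2, var2, cv2 = om.windowed_variability(t2, spec, "pupil_size")
        assert cv2 == pytest.approx(cv1)
        assert sd2 == pytest.approx(3.5 * sd1)
        assert var2 == pytest.approx(3.5**2 * var1)

    def test_too_few_valid_samples_sentinel(self):
        valid = np.zeros(700, bool)
        valid[250] = True
        t = make_trace(np.full(700, 30.0), valid=valid)
        sd, var, cv = om.windowed_variability(t, om.WindowSpec.named("early"), "pupil_size")
        assert np.isnan(sd) and np.isnan(var) and np.isnan(cv)


class TestSessionFeatureVector:
    @pytest.fixture()
    def pair(self):
        return simulate_binocular(TraceParams(rng_seed=8))

    def test_identical_pre_post_zero_diffs(self, pair):
        fv = om.session_feature_vector(pair, pair, 40.0, 40.0)
        for name, value in fv.diff.items():
            if np.isfinite(value):
                assert value == 0.0

    def test_cff_difference(self, pair):
        fv = om.session_feature_vector(pair, pair, 40.0, 37.03)
        assert fv.diff["cff"] == pytest.approx(-2.97)

    def test_missing_cff_is_nan(self, pair):
        fv = om.session_feature_vector(pair, pair)
        assert np.isnan(fv.diff["cff"])

    def test_antisymmetry(self):
        pre = simulate_binocular(TraceParams(rng_seed=21))
        post = simulate_binocular(TraceParams(rng_seed=22))
        fwd = om.session_feature_vector(pre, post, 40.0, 38.0)
        rev = om.session_feature_vector(post, pre, 38.0, 40.0)
        for name in fwd.diff:
            if np.isfinite(fwd.diff[name]):
                assert rev.diff[name] == pytest.approx(-fwd.diff[name], abs=1e-9)

    def test_first_200_frames_ignored(self):
        pair = simulate_binocular(TraceParams(rng_seed=9))
        ref = om.session_feature_vector(pair, pair, 40.0, 40.0)
        mutated = {eye: t.copy() for eye, t in pair.items()}
        for t in mutated.values():
            t.fissure_length[:200] = 0.0
            t.pupil_diameter[:200] = np.nan
            t.valid[:200] = False
        out = om.session_feature_vector(mutated, mutated, 40.0, 40.0)
        for name in ref.pre:
            if np.isfinite(ref.pre[name]):
                assert out.pre[name] == pytest.approx(ref.pre[name], abs=1e-9)

    def test_blink_rate_delta_recovered(self):
        # post simulated with +6 blinks/min; the extracted difference
        # should land within 1/min of the injected shift
        import dataclasses

        base = TraceParams(rng_seed=30)
        pre = simulate_binocular(base)
        post = simulate_binocular(dataclasses.replace(base, blink_rate=21.0, rng_seed=31))
        fv = om.session_feature_vector(pre, post, 40.0, 40.0)
        # blink counts inside [200, 1800) suffer edge effects of +-1 event
        assert fv.diff["blink_times_per_min"] == pytest.approx(6.0, abs=1.5)

    def test_row_schema(self, pair):
        fv = om.session_feature_vector(pair, pair, 40.0, 40.0)
        row = fv.to_row()
        assert len(row) == 3 * len(om.FEATURE_NAMES)
        assert "fissure_length_cv_mid_diff" in row
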