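import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from pulmowk.waveforms import (
    PressureSummary,
    Waveform,
    compute_features,
    net_volume,
    read_waveform_csv,
    regurgitant_volume,
    resample,
    scale_to_stroke_volume,
    stroke_volume,
    write_waveform_csv,
)


def uniform_waveform(values, period=1.0, kind="flow"):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * (period / values.size)
    return Waveform(times=t, values=values, period=period, kind=kind)


class TestValidation:
    def test_rejects_too_few_samples(self):
        with pytest.raises(ValueError, match="16 samples"):
            uniform_waveform(np.ones(8))

    def test_rejects_non_monotone_times(self):
        t = np.linspace(0, 0.9, 20)
        t[5] = t[7]
        with pytest.raises(ValueError, match="strictly increasing"):
            Waveform(times=t, values=np.ones(20), period=1.0)

    def test_rejects_endpoint_at_period(self):
        t = np.linspace(0.0, 1.0, 20)
        with pytest.raises(ValueError, match="< period"):
            Waveform(times=t, values=np.ones(20), period=1.0)


class TestFeatures:
    def test_constant_flow(self):
        q = 5.0 * 1e-3 / 60.0  # 5 l/min
        w = uniform_waveform(np.full(32, q))
        f = compute_features(w)
        assert f.mean_flow == pytest.approx(q)
        assert f.max_flow == pytest.approx(q)
        assert f.min_flow == pytest.approx(q)
        assert f.regurgitant_volume == 0.0
        assert f.delta_t > 0

    def test_sine_extrema_and_delta_t(self):
        n = 400
        t = np.arange(n) / n
        w = Waveform(times=t, values=1e-6 * np.sin(2 * np.pi * t), period=1.0)
        f = compute_features(w)
        assert f.t_at_max == pytest.approx(0.25, abs=1 / n)
        assert f.t_at_min == pytest.approx(0.75, abs=1 / n)
        assert f.delta_t == pytest.approx(0.5, abs=2 / n)
        assert f.mean_flow == pytest.approx(0.0, abs=1e-12)

    def test_delta_t_wraps_when_minimum_precedes_maximum(self):
        n = 400
        t = np.arange(n) / n
        # maximum at 0.75, next minimum (periodically) at 0.25
        w = Waveform(times=t, values=1e-6 * np.sin(2 * np.pi * (t - 0.5)), period=1.0)
        f = compute_features(w)
        assert f.t_at_max == pytest.approx(0.75, abs=1 / n)
        assert f.delta_t == pytest.approx(0.5, abs=2 / n)

    def test_lobe_volumes_match_adaptive_quadrature(self):
        # half-sine systolic lobe (peak 300 ml/s over 0.3 s) plus a negative
        # triangular lobe of area 5 ml
        peak, ts = 300e-6, 0.3

        def q_of_t(tt):
            if tt < ts:
                return peak * np.sin(np.pi * tt / ts)
            if 0.4 <= tt < 0.6:
                return -50e-6 * (1 - abs(tt - 0.5) / 0.1)
            return 0.0

        n = 4096
        t = np.arange(n) / n
        w = Waveform(times=t, values=np.array([q_of_t(x) for x in t]), period=1.0)
        sv_ref, _ = quad(lambda x: max(q_of_t(x), 0.0), 0, 1, limit=200)
        rv_ref, _ = quad(lambda x: max(-q_of_t(x), 0.0), 0, 1, limit=200)
        assert sv_ref == pytest.approx(2 / np.pi * peak * ts, rel=1e-6)
        assert stroke_volume(w) == pytest.approx(sv_ref, rel=1e-4)
        assert regurgitant_volume(w) == pytest.approx(rv_ref, rel=1e-4)
        assert rv_ref == pytest.approx(5e-6, rel=1e-4)

    def test_triangular_negative_lobe_is_exact(self):
        # piecewise-linear waveform: quadrature must be exact (zero crossings
        # are interpolated linearly)
        t = np.array([0.0, 0.1, 0.35, 0.45, 0.55, 0.7, 0.9])
        v = np.array([0.0, 200e-6, 0.0, -50e-6, 0.0, 0.0, 0.0])
        # piecewise-linear refinement sharing the breakpoints (>= 16 samples)
        tt = np.sort(np.unique(np.concatenate([np.linspace(0, 0.99, 20), t])))
        vv = np.interp(tt, np.append(t, 1.0), np.append(v, 0.0))
        w = Waveform(times=tt, values=vv, period=1.0)
        assert regurgitant_volume(w) == pytest.approx(0.5 * 0.2 * 50e-6, rel=1e-12)

    def test_all_positive_waveform_has_zero_regurgitation(self):
        w = uniform_waveform(np.abs(np.sin(2 * np.pi * np.arange(64) / 64)) + 0.1)
        assert regurgitant_volume(w) == 0.0

    def test_constant_negative_flow(self):
        w = uniform_waveform(np.full(32, -1e-6))
        assert regurgitant_volume(w) == pytest.approx(1e-6, rel=1e-12)


class TestScaling:
    def test_identity_when_volume_matches(self):
        w = uniform_waveform(np.abs(np.sin(np.pi * np.arange(64) / 64)))
        target = net_volume(w)
        np.testing.assert_allclose(scale_to_stroke_volume(w, target).values, w.values)

    def test_doubling(self):
        w = uniform_waveform(np.abs(np.sin(np.pi * np.arange(64) / 64)))
        w2 = scale_to_stroke_volume(w, 2 * net_volume(w))
        np.testing.assert_allclose(w2.values, 2 * w.values)

    def test_scaled_volume_hits_clinical_stroke_volume(self):
        # characteristic control-shaped waveform scaled to a 69 ml beat
        w = uniform_waveform(np.abs(np.sin(np.pi * np.arange(128) / 128)) ** 2)
        scaled = scale_to_stroke_volume(w, 69e-6)
        assert net_volume(scaled) == pytest.approx(69e-6, rel=1e-12)

    def test_rejects_nonpositive_net_volume(self):
        w = uniform_waveform(np.full(32, -1.0))
        with pytest.raises(ValueError, match="net forward volume"):
            scale_to_stroke_volume(w, 70e-6)

    @given(st.floats(min_value=1e-6, max_value=1e-4))
    @settings(max_examples=25, deadline=None)
    def test_scaling_is_idempotent(self, target):
        w = uniform_waveform(np.abs(np.sin(np.pi * np.arange(64) / 64)) + 0.05)
        once = scale_to_stroke_volume(w, target)
        twice = scale_to_stroke_volume(once, target)
        np.testing.assert_allclose(once.values, twice.values, rtol=1e-14)


class TestResample:
    def test_constant_stays_constant(self):
        w = uniform_waveform(np.full(32, 3.3e-6))
        for method in ("linear", "fourier"):
            out = resample(w, 200, method=method)
            np.testing.assert_allclose(out.values, 3.3e-6, rtol=1e-12)

    def test_identity_on_original_grid(self):
        w = uniform_waveform(np.sin(2 * np.pi * np.arange(64) / 64))
        out = resample(w, 64)
        np.testing.assert_allclose(out.values, w.values, atol=1e-12)

    def test_sine_net_volume_preserved(self):
        n = 64
        t = np.arange(n) / n
        w = Waveform(times=t, values=2e-6 + 1e-6 * np.sin(2 * np.pi * t), period=1.0)
        for method, tol in (("fourier", 1e-9), ("linear", 1e-3)):
            out = resample(w, 256, method=method)
            assert net_volume(out) == pytest.approx(2e-6, rel=tol)

    def test_rejects_small_n(self):
        w = uniform_waveform(np.ones(32))
        with pytest.raises(ValueError):
            resample(w, 8)


class TestInvariants:
    @given(st.integers(min_value=0, max_value=1000))
    @settings(max_examples=30, deadline=None)
    def test_signed_volume_identity(self, seed):
        rng = np.random.default_rng(seed)
        w = uniform_waveform(rng.normal(size=48) * 1e-6)
        assert stroke_volume(w) - regurgitant_volume(w) == pytest.approx(
            net_volume(w), abs=1e-18
        )

    @given(st.integers(min_value=1, max_value=47))
    @settings(max_examples=30, deadline=None)
    def test_regurgitant_volume_time_shift_invariant(self, shift):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=48) * 1e-6
        w = uniform_waveform(vals)
        w_shift = uniform_waveform(np.roll(vals, shift))
        assert regurgitant_volume(w_shift) == pytest.approx(
            regurgitant_volume(w), rel=1e-12
        )


class TestPressureSummary:
    def test_orders_fields(self):
        with pytest.raises(ValueError):
            PressureSummary(p_sys=10.0, p_dias=20.0, p_mean=15.0)

    def test_from_trace(self):
        t = np.linspace(0, 1, 101)
        p = 100 + 10 * np.sin(2 * np.pi * t)
        s = PressureSummary.from_trace(t, p)
        assert s.p_sys == pytest.approx(110, rel=1e-3)
        assert s.p_dias == pytest.approx(90, rel=1e-3)
        assert s.p_mean == pytest.approx(100, rel=1e-6)
        assert s.pulse == pytest.approx(20, rel=1e-3)


def test_csv_round_trip(tmp_path):
    w = uniform_waveform(np.sin(2 * np.pi * np.arange(64) / 64) * 1e-4, period=0.8)
    path = tmp_path / "w.csv"
    write_waveform_csv(w, path)
    back = read_waveform_csv(path)
    assert back.period == pytest.approx(0.8, rel=1e-9)
    np.testing.assert_allclose(back.values, w.values, rtol=1e-12)
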