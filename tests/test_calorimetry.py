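import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import butter, freqz

import wearcal as wc
from wearcal.calorimetry import UniformEnergySeries, _trapz_between

from oracles import brute_hampel


class TestWeirRate:
    @pytest.mark.parametrize(
        "vo2, vco2, expected",
        [
            (0.0, 0.0, 0.0),
            (0.3, 0.24, 1.4487),  # 3.941*0.3 + 1.11*0.24
            (1.0, 0.0, 3.941),
            (0.0, 1.0, 1.11),
        ],
    )
    def test_hand_values(self, vo2, vco2, expected):
        assert wc.weir_rate(vo2, vco2) == pytest.approx(expected, abs=1e-12)

    def test_linear_and_vectorised(self, rng):
        vo2 = rng.uniform(0.2, 3.0, 50)
        vco2 = rng.uniform(0.2, 3.0, 50)
        np.testing.assert_allclose(
            wc.weir_rate(2 * vo2, 2 * vco2), 2 * wc.weir_rate(vo2, vco2), rtol=1e-12
        )

    def test_reporting_scale_toggle(self):
        coeffs = wc.WeirCoefficients(apply_scale=True)
        assert wc.weir_rate(1.0, 0.0, coeffs) == pytest.approx(3.941 * 1.1440)

    @pytest.mark.parametrize("vo2, vco2", [(-0.1, 0.2), (0.2, -0.1), (np.nan, 0.1)])
    def test_invalid_gas_rejected(self, vo2, vco2):
        with pytest.raises(ValueError):
            wc.weir_rate(vo2, vco2)


class TestHampel:
    def test_single_spike_replaced(self):
        clean, flagged = wc.hampel_replace([1, 1, 1, 100, 1, 1, 1])
        np.testing.assert_array_equal(clean, np.ones(7))
        np.testing.assert_array_equal(flagged, [3])

    def test_constant_series_untouched(self):
        clean, flagged = wc.hampel_replace([2.5] * 20)
        np.testing.assert_array_equal(clean, [2.5] * 20)
        assert flagged.size == 0

    def test_short_series_pass_through(self):
        clean, flagged = wc.hampel_replace([1.0, 50.0, 1.0])
        np.testing.assert_array_equal(clean, [1.0, 50.0, 1.0])
        assert flagged.size == 0

    def test_empty_input(self):
        clean, flagged = wc.hampel_replace([])
        assert clean.size == 0 and flagged.size == 0

    @pytest.mark.parametrize("dispersion", ["mad", "sd"])
    def test_matches_brute_force_oracle(self, rng, dispersion):
        """Exact equivalence with an independent sliding-window implementation."""
        config = wc.HampelConfig(dispersion=dispersion)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            x = rng.normal(5, 1, n)
            spikes = rng.random(n) < 0.05
            x[spikes] *= 8
            got, got_idx = wc.hampel_replace(x, config)
            want, want_idx = brute_hampel(x, dispersion=dispersion)
            np.testing.assert_array_equal(got, want)
            np.testing.assert_array_equal(got_idx, want_idx)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=0, max_size=40), st.integers(1, 4))
    def test_property_changes_only_flagged(self, values, half_window):
        config = wc.HampelConfig(half_window=half_window)
        clean, flagged = wc.hampel_replace(values, config)
        untouched = np.setdiff1d(np.arange(len(values)), flagged)
        np.testing.assert_array_equal(clean[untouched], np.asarray(values)[untouched])


class TestSplineResample:
    def test_integer_grid_passthrough(self):
        t = np.arange(0, 20, dtype=float)
        v = np.sin(t / 3.0)
        out = wc.spline_resample_1hz(t, v)
        assert out.t0 == 0.0
        np.testing.assert_allclose(out.rate, v, atol=1e-12)

    def test_exact_cubic_reconstruction(self, rng):
        poly = lambda t: 0.5 * t**3 - 2 * t**2 + t + 4
        t = np.sort(rng.uniform(0, 30, 40))
        out = wc.spline_resample_1hz(t, poly(t))
        np.testing.assert_allclose(out.rate, poly(out.times), atol=1e-8)

    def test_linear_ramp_midpoint(self, rng):
        t = np.unique(np.concatenate([[0.0, 100.0], np.sort(rng.uniform(0, 100, 30))]))
        v = t / 10.0  # 0 -> 10 over 100 s
        out = wc.spline_resample_1hz(t, v)
        assert out.rate[int(50 - out.t0)] == pytest.approx(5.0, abs=1e-9)

    def test_no_extrapolation(self):
        t = np.array([0.4, 1.7, 3.1, 4.9, 6.6])
        out = wc.spline_resample_1hz(t, np.ones_like(t))
        assert out.t0 == 1.0 and out.times[-1] == 6.0

    def test_rejects_unsorted_and_short(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            wc.spline_resample_1hz([0, 2, 1, 3], [1, 1, 1, 1])
        with pytest.raises(ValueError, match="at least 4"):
            wc.spline_resample_1hz([0, 1, 2], [1, 1, 1])


class TestButterworth:
    def test_dc_gain_unity(self):
        series = UniformEnergySeries(0.0, np.full(300, 2.5))
        for phase in ("zero_phase", "causal"):
            out = wc.butterworth_lowpass(series, wc.FilterConfig(phase=phase))
            np.testing.assert_allclose(out.rate, 2.5, atol=1e-6)

    @staticmethod
    def _steady_amplitude(y, freq):
        # project the last two-thirds onto the quadrature pair at freq
        n = y.size
        tail = y[n // 3:] - np.mean(y[n // 3:])
        t = np.arange(tail.size)
        c = tail @ np.cos(2 * np.pi * freq * t)
        s = tail @ np.sin(2 * np.pi * freq * t)
        return 2.0 * np.hypot(c, s) / tail.size

    def test_cutoff_attenuation_causal(self):
        t = np.arange(3000, dtype=float)
        series = UniformEnergySeries(0.0, np.sin(2 * np.pi * 0.04 * t))
        out = wc.butterworth_lowpass(series, wc.FilterConfig(phase="causal"))
        assert self._steady_amplitude(out.rate, 0.04) == pytest.approx(0.7071, abs=0.01)

    def test_stopband_attenuation(self):
        t = np.arange(3000, dtype=float)
        series = UniformEnergySeries(0.0, np.sin(2 * np.pi * 0.4 * t))
        out = wc.butterworth_lowpass(series, wc.FilterConfig(phase="causal"))
        assert self._steady_amplitude(out.rate, 0.4) < 1e-3

    def test_magnitude_response_never_exceeds_unity(self):
        b, a = butter(4, 0.04, btype="low", fs=1.0)
        _, h = freqz(b, a, worN=2048)
        assert np.max(np.abs(h)) <= 1.0 + 1e-9

    def test_too_short_rejected(self):
        series = UniformEnergySeries(0.0, np.ones(10))
        with pytest.raises(ValueError, match="need at least"):
            wc.butterworth_lowpass(series)


class TestSegmentEnergy:
    def test_constant_rate_times_duration(self, cad_protocol):
        series = UniformEnergySeries(0.0, np.full(2341, 1.2))
        segs, total = wc.segment_energy(series, cad_protocol)
        typing = next(s for s in segs if s.activity_id == "typing")  # 180 s
        assert typing.ee_kcal == pytest.approx(3.6, abs=1e-9)
        assert total == pytest.approx(1.2 * 2340 / 60.0, abs=1e-9)
        for s in segs:
            dur_min = cad_protocol.segment(s.activity_id).duration_s / 60.0
            assert s.ee_kcal == pytest.approx(s.ee_rate_kcal_min * dur_min, abs=1e-9)

    def test_contiguous_segments_add(self, rng):
        series = UniformEnergySeries(0.0, rng.uniform(1, 5, 400))
        whole = _trapz_between(series, 10.0, 300.0)
        parts = _trapz_between(series, 10.0, 137.0) + _trapz_between(series, 137.0, 300.0)
        assert whole == pytest.approx(parts, abs=1e-9)

    def test_segment_beyond_support_named(self, cad_protocol):
        series = UniformEnergySeries(0.0, np.ones(500))
        with pytest.raises(ValueError, match="typing"):
            wc.segment_energy(series, cad_protocol)


class TestProcessTrace:
    def test_zero_gas_gives_zero_energy(self, cad_protocol):
        t = np.arange(-10.0, 2360.0, 2.0)
        trace = wc.GasExchangeTrace("p0", t, np.zeros_like(t), np.zeros_like(t))
        out = wc.process_trace(trace, cad_protocol)
        assert out.total_kcal == pytest.approx(0.0, abs=1e-9)
        assert all(abs(s.ee_kcal) < 1e-9 for s in out.segments)

    def test_linearity_in_gas_volumes(self, noise_free_record):
        rec = noise_free_record
        out1 = wc.process_trace(rec.trace, rec.protocol)
        scaled = wc.GasExchangeTrace(
            rec.trace.patient_id, rec.trace.times, 3.0 * rec.trace.vo2, 3.0 * rec.trace.vco2
        )
        out3 = wc.process_trace(scaled, rec.protocol)
        for s1, s3 in zip(out1.segments, out3.segments):
            assert s3.ee_kcal == pytest.approx(3.0 * s1.ee_kcal, abs=1e-9)

    def test_noise_free_matches_truth(self, noise_free_record):
        rec = noise_free_record
        out = wc.process_trace(rec.trace, rec.protocol)
        for seg in out.segments:
            truth = rec.trace.truth_ee_per_segment[seg.activity_id]
            assert seg.ee_kcal == pytest.approx(truth, rel=0.02)

    def test_spike_removed_by_hampel_stage(self, noise_free_record):
        rec = noise_free_record
        i = rec.trace.times.size // 2
        vo2 = rec.trace.vo2.copy()
        vco2 = rec.trace.vco2.copy()
        vo2[i] *= 10
        vco2[i] *= 10
        spiky = wc.GasExchangeTrace(rec.trace.patient_id, rec.trace.times, vo2, vco2)
        base = wc.process_trace(rec.trace, rec.protocol).total_kcal
        with_spike = wc.process_trace(spiky, rec.protocol).total_kcal
        assert abs(with_spike - base) / base < 0.005

    def test_filter_before_hampel_is_worse_on_spikes(self, noise_free_record):
        """Permuting the stage order lets spikes leak through the spline+filter."""
        rec = noise_free_record
        rng = np.random.default_rng(5)
        vo2 = rec.trace.vo2.copy()
        vco2 = rec.trace.vco2.copy()
        idx = rng.choice(np.arange(100, vo2.size - 100), size=12, replace=False)
        vo2[idx] *= 10
        vco2[idx] *= 10
        spiky = wc.GasExchangeTrace(rec.trace.patient_id, rec.trace.times, vo2, vco2)
        truth = rec.trace.truth_ee_total_kcal

        correct = wc.process_trace(spiky, rec.protocol).total_kcal

        # permuted: spline + filter first, Hampel on the 1 Hz series afterwards
        raw = wc.weir_rate(spiky.vo2, spiky.vco2)
        series = wc.butterworth_lowpass(wc.spline_resample_1hz(spiky.times, raw))
        cleaned, _ = wc.hampel_replace(series.rate)
        permuted_series = UniformEnergySeries(series.t0, cleaned)
        _, permuted = wc.segment_energy(permuted_series, rec.protocol)

        assert abs(correct - truth) < abs(permuted - truth)

    def test_stage_errors_annotated(self, cad_protocol):
        t = np.arange(0.0, 50.0, 2.0)
        short = wc.GasExchangeTrace("p0", t, np.ones_like(t), np.ones_like(t))
        with pytest.raises(ValueError, match="integration stage"):
            wc.process_trace(short, cad_protocol)
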