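import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from avsynch.waveform import (
    BeatTiming,
    WaveletComponent,
    a3_train,
    beat_components,
    effective_a3_end,
    half_support_ms,
    ricker,
    synthesize_beat,
)


class TestRicker:
    def test_unity_at_origin(self):
        assert ricker(0.0, 20.0) == pytest.approx(1.0)

    def test_root_of_leading_factor(self):
        # 1 - 2*pi^2*f^2*t^2 = 0  at  t = 1/(sqrt(2)*pi*f)
        t_ms = 1000.0 / (math.sqrt(2.0) * math.pi * 20.0)
        assert ricker(t_ms, 20.0) == pytest.approx(0.0, abs=1e-12)

    def test_known_value_at_5ms(self):
        # frozen from an independent high-precision evaluation
        assert ricker(5.0, 20.0) == pytest.approx(0.7272, abs=1e-3)

    def test_even_function(self):
        t = np.linspace(0.1, 100.0, 57)
        np.testing.assert_allclose(ricker(t, 20.0), ricker(-t, 20.0))

    @pytest.mark.parametrize("f", [0.0, -3.0])
    def test_nonpositive_frequency_rejected(self, f):
        with pytest.raises(ValueError):
            ricker(1.0, f)

    @given(
        t=st.floats(-500, 500, allow_nan=False),
        f=st.floats(1.0, 100.0, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_range(self, t, f):
        v = ricker(t, f)
        assert -2.0 * math.exp(-1.5) - 1e-12 <= v <= 1.0 + 1e-12


class TestSynthesizeBeat:
    def test_single_component_max(self):
        comp = [WaveletComponent("A3", 2.0, 500.0)]
        trace = synthesize_beat(comp, BeatTiming(a3_signal_end_ms=650.0))
        i = int(np.argmax(trace.samples))
        assert trace.samples[i] == pytest.approx(2.0, abs=1e-6)
        assert abs(trace.times_ms[i] - 500.0) <= trace.sample_period_ms

    def test_disjoint_components_two_maxima_no_a7(self):
        comps = [
            WaveletComponent("A3", 2.0, 500.0),
            WaveletComponent("A4", 3.0, 850.0),
        ]
        timing = BeatTiming(a3_signal_end_ms=650.0)
        trace = synthesize_beat(comps, timing)
        t = trace.times_ms
        assert trace.samples[(t > 400) & (t < 650)].max() == pytest.approx(2.0, abs=1e-3)
        assert trace.samples[(t > 700) & (t < 1000)].max() == pytest.approx(3.0, abs=1e-3)
        assert trace.ground_truth["a7"] is False

    def test_coincident_peaks_sum_and_flag_a7(self):
        comps = [
            WaveletComponent("A3", 2.0, 850.0),
            WaveletComponent("A4", 3.0, 850.0),
        ]
        trace = synthesize_beat(comps, BeatTiming(a3_signal_end_ms=900.0))
        assert trace.samples.max() == pytest.approx(5.0, abs=1e-6)
        assert trace.ground_truth["a7"] is True

    def test_rectified_nonnegative(self):
        comps, _ = beat_components(2.0, 3.0, 600.0, BeatTiming())
        trace = synthesize_beat(comps, BeatTiming())
        assert (trace.samples >= 0).all()

    def test_linearity_before_rectification(self):
        timing = BeatTiming(a3_signal_end_ms=700.0)
        comps, _ = beat_components(1.5, 2.5, 500.0, timing)
        scaled = [
            WaveletComponent(c.label, 3.0 * c.peak_amplitude, c.peak_time_ms,
                             c.peak_frequency_hz)
            for c in comps
        ]
        t1 = synthesize_beat(comps, timing, duration_ms=1200.0)
        t2 = synthesize_beat(scaled, timing, duration_ms=1200.0)
        np.testing.assert_allclose(t2.raw_samples, 3.0 * t1.raw_samples, atol=1e-12)

    def test_deterministic_without_jitter(self):
        timing = BeatTiming(a3_signal_end_ms=750.0, a3_end_variation_sd_ms=0.0)
        comps, _ = beat_components(2.0, 3.0, 600.0, timing)
        t1 = synthesize_beat(comps, timing, duration_ms=1200.0)
        t2 = synthesize_beat(comps, timing, duration_ms=1200.0)
        np.testing.assert_array_equal(t1.samples, t2.samples)

    def test_aliasing_guard(self):
        comps = [WaveletComponent("A3", 1.0, 500.0, 20.0)]
        with pytest.raises(ValueError, match="alias"):
            synthesize_beat(comps, BeatTiming(), sampling_rate_hz=60.0)

    def test_jitter_requires_rng(self):
        timing = BeatTiming(a3_end_variation_sd_ms=17.0)
        comps = [WaveletComponent("A3", 1.0, 500.0)]
        with pytest.raises(ValueError, match="rng"):
            synthesize_beat(comps, timing)

    @pytest.mark.parametrize("sd", [17.0, 33.0])
    def test_jitter_sd_matches_configuration(self, sd, rng):
        timing = BeatTiming(a3_end_variation_sd_ms=sd)
        ends = np.array(
            [effective_a3_end(timing, None, rng) for _ in range(10_000)]
        )
        assert np.std(ends) == pytest.approx(sd, rel=0.10)
        # and the trace path applies the same draw to the rendered train
        comps = a3_train(2.0, timing, timing.a3_signal_end_ms)
        trace = synthesize_beat(comps, timing, rng=rng)
        assert trace.ground_truth["a3_end_ms"] != timing.a3_signal_end_ms


class TestBeatComponents:
    def test_a7_flag_follows_overlap(self):
        timing = BeatTiming(a3_signal_end_ms=650.0)
        # A4 starts at p + 90; overlap iff start < a3 end
        _, meta_far = beat_components(2.0, 3.0, 700.0, timing)
        _, meta_near = beat_components(2.0, 3.0, 400.0, timing)
        assert meta_far["a7"] is False
        assert meta_near["a7"] is True

    def test_train_is_anchored_at_signal_end(self):
        timing = BeatTiming(a3_signal_end_ms=800.0)
        lobes = a3_train(2.0, timing)
        assert lobes[-1].peak_time_ms == pytest.approx(
            800.0 - timing.a3_peak_offset_ms
        )
        # uniform spacing; amplitudes decay to the configured fraction
        peaks = [c.peak_time_ms for c in lobes]
        assert np.allclose(np.diff(peaks), timing.a3_lobe_spacing_ms)
        assert lobes[-1].peak_amplitude == pytest.approx(
            timing.a3_end_fraction * lobes[0].peak_amplitude
        )

    def test_isolated_lobe_peak_amplitude_preserved(self):
        # no overlapping support from other families -> rectified max equals
        # the component amplitude (within one sample period of peak shift)
        timing = BeatTiming(a3_signal_end_ms=700.0)
        lobes = a3_train(2.0, timing)
        trace = synthesize_beat(lobes, timing, duration_ms=900.0)
        assert trace.samples.max() == pytest.approx(2.0, abs=0.01)

    def test_rate_adjustment_shortens_end(self):
        timing = BeatTiming(
            a3_signal_end_ms=800.0, auto_adjust_a3_end_with_rate=True
        )
        assert effective_a3_end(timing, 1100.0) == pytest.approx(800.0)
        assert effective_a3_end(timing, 800.0) == pytest.approx(640.0)
        # floored at a2_delay + 100
        assert effective_a3_end(timing, 350.0) == pytest.approx(400.0)


class TestValidation:
    def test_component_label(self):
        with pytest.raises(ValueError):
            WaveletComponent("A9", 1.0, 100.0)

    def test_negative_amplitude(self):
        with pytest.raises(ValueError):
            WaveletComponent("A3", -1.0, 100.0)

    def test_timing_sd_choices(self):
        with pytest.raises(ValueError):
            BeatTiming(a3_end_variation_sd_ms=25.0)

    def test_half_support(self):
        assert half_support_ms(20.0) == pytest.approx(125.0)
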