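"""Template construction, event detection, statistics, RMP and QC."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from synastro import ephys_events as ee
from synastro import synthio
from synastro.trace import Trace

from conftest import FS, insert_events


def _aligned_dev(template, kernel):
    """Max deviation between template and kernel, peak-aligned."""
    ip = template.i_peak
    kp = int(np.argmax(np.abs(kernel)))
    n = min(template.waveform.size - ip, kernel.size - kp)
    return np.max(np.abs(template.waveform[ip : ip + n] - kernel[kp : kp + n]))


class TestBuildTemplate:
    def test_identical_noiseless_events_recover_kernel(self, kernel):
        trace = insert_events(60, np.arange(2, 60, 3.9)[:15], 30.0, kernel)
        template = ee.build_template([trace], 15)
        assert template.n_source_events == 15
        assert _aligned_dev(template, kernel) < 1e-9

    def test_amplitude_jittered_events_recover_kernel(self, kernel):
        rng = np.random.default_rng(0)
        amps = 25 * (0.8 + 0.4 * rng.random(15))
        trace = insert_events(60, np.arange(2, 60, 4.0)[:15], amps, kernel)
        template = ee.build_template([trace], 15)
        assert _aligned_dev(template, kernel) < 1e-6

    def test_too_few_candidate_events_is_explicit_error(self, kernel):
        trace = insert_events(60, [5, 15, 25, 35], 30.0, kernel)
        with pytest.raises(ValueError, match="4 candidate events"):
            ee.build_template([trace], 15)

    def test_probe_scaling_leaves_template_unchanged(self, kernel):
        rng = np.random.default_rng(1)
        amps = 20 * (0.8 + 0.4 * rng.random(12))
        trace = insert_events(60, np.arange(2, 50, 4.0)[:12], amps, kernel)
        scaled = Trace((trace.samples + 100) * 5.0 - 100, FS, "pA")
        t1 = ee.build_template([trace], 12)
        t2 = ee.build_template([scaled], 12)
        np.testing.assert_allclose(t1.waveform, t2.waveform, atol=1e-9)

    def test_target_out_of_bounds(self, kernel):
        trace = insert_events(60, np.arange(2, 60, 4.0)[:14], 30.0, kernel)
        with pytest.raises(ValueError):
            ee.build_template([trace], 9)
        with pytest.raises(ValueError):
            ee.build_template([trace], 21)


@pytest.fixture(scope="module")
def template(kinetics):
    return ee.EventTemplate.from_kinetics(kinetics, FS)


class TestDetectEvents:
    def test_noiseless_events_detected_exactly(self, kernel, template):
        trace = insert_events(10, [2.0, 5.0, 8.0], 30.0, kernel)
        events = ee.detect_events(trace, template, analysis_window_s=10)
        assert len(events) == 3
        kernel_time_to_peak = np.argmax(np.abs(kernel)) / FS
        for ev, t0 in zip(events, [2.0, 5.0, 8.0]):
            assert ev.amplitude == pytest.approx(-30.0, abs=0.1)
            assert ev.peak_time == pytest.approx(t0 + kernel_time_to_peak, abs=0.002)

    def test_subthreshold_event_discarded_with_audit(self, kernel, template):
        trace = insert_events(10, [5.0], 8.0, kernel)
        events, audit = ee.detect_events(trace, template, analysis_window_s=10,
                                         return_audit=True)
        assert events == []
        assert (audit["reason"] == "below_amplitude_floor").any()

    def test_voltage_trace_rejected(self, template):
        trace = Trace(np.zeros(int(FS)), FS, "mV")
        with pytest.raises(ValueError, match="pA"):
            ee.detect_events(trace, template, analysis_window_s=1)

    def test_window_longer_than_trace_rejected(self, kernel, template):
        trace = insert_events(10, [5.0], 30.0, kernel)
        with pytest.raises(ValueError, match="window"):
            ee.detect_events(trace, template, analysis_window_s=60)

    def test_noiseless_oracle_equivalence(self, kinetics, template):
        # amplitudes straddling the floor: only >=10 pA survive
        trace, truth = synthio.gen_event_trace(
            60, 0.3, 12.0, 3.0, kinetics, noise_sd_pA=0.0, seed=7
        )
        events = ee.detect_events(trace, template)
        expected = truth.event_times_s[np.abs(truth.event_amplitudes_pA) >= 10.0]
        # tolerate truth events merged by overlap (<1 exclusion span apart)
        gaps = np.diff(expected, prepend=-1.0)
        expected = expected[gaps > template.exclusion_s]
        det = np.array([e.onset_time for e in events])
        assert det.size == expected.size
        assert np.all(np.abs(det - expected) < 0.005)

    def test_threshold_monotonicity(self, kinetics):
        trace, _ = synthio.gen_event_trace(60, 0.5, 18, 4, kinetics, noise_sd_pA=2, seed=3)
        template = ee.EventTemplate.from_kinetics(kinetics, FS)
        counts = [
            len(ee.detect_events(trace, template, amplitude_threshold_pA=thr))
            for thr in [0.0, 5.0, 10.0, 15.0, 20.0, 30.0]
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_sensitivity_and_false_positives_vs_truth(self, kinetics):
        trace, truth = synthio.gen_event_trace(
            600, 0.5, 20.0, 1.5, kinetics, noise_sd_pA=2.0, seed=42
        )
        template = ee.EventTemplate.from_kinetics(kinetics, FS)
        events = ee.detect_events(trace, template, analysis_window_s=600)
        det = np.array([e.onset_time for e in events])
        matched = 0
        used = np.zeros(det.size, dtype=bool)
        for t0 in truth.event_times_s:
            close = np.nonzero((np.abs(det - t0) < 0.005) & ~used)[0]
            if close.size:
                used[close[0]] = True
                matched += 1
        sensitivity = matched / truth.event_times_s.size
        fp_rate = (det.size - matched) / 600.0
        assert sensitivity >= 0.95
        assert fp_rate <= 0.02


class TestEventStatistics:
    def test_frequency_and_means(self):
        events = [
            ee.DetectedEvent(i * 2.0, i * 2.0 + 0.003, amp, 1.5, 8.0, 20.0)
            for i, amp in zip(range(2), [-20.0, -24.0])
        ]
        stats = ee.event_statistics(events, 60.0)
        assert stats.mean_amplitude_pA == pytest.approx(-22.0)
        assert stats.frequency_hz == pytest.approx(2 / 60)

    def test_thirty_events_in_a_minute_is_half_hertz(self):
        events = [
            ee.DetectedEvent(i * 1.9, i * 1.9 + 0.003, -20.0, 1.5, 8.0, 20.0)
            for i in range(30)
        ]
        assert ee.event_statistics(events, 60.0).frequency_hz == pytest.approx(0.5)

    def test_empty_events_flagged_absent_not_zero(self):
        stats = ee.event_statistics([], 60.0)
        assert stats.frequency_hz == 0.0
        assert stats.mean_amplitude_pA is None
        assert stats.mean_rise_ms is None

    def test_event_outside_window_rejected(self):
        ev = ee.DetectedEvent(70.0, 70.003, -20.0, 1.5, 8.0, 20.0)
        with pytest.raises(ValueError):
            ee.event_statistics([ev], 60.0)

    def test_decay_tau_recovered_from_noiseless_kernel(self, kernel, kinetics):
        trace = insert_events(10, [2.0, 5.0], 30.0, kernel)
        template = ee.EventTemplate.from_kinetics(kinetics, FS)
        events = ee.detect_events(trace, template, analysis_window_s=10)
        stats = ee.event_statistics(events, 10.0)
        assert stats.mean_decay_ms == pytest.approx(kinetics.decay_tau_ms, abs=0.2)


class TestRestingPotential:
    def test_constant_potential(self):
        trace = Trace(np.full(10_000, -56.18), FS, "mV")
        assert ee.resting_membrane_potential(trace) == pytest.approx(-56.18)

    def test_spike_masked_before_averaging(self):
        y = np.full(10_000, -60.0)
        y[5_000:5_020] = -20.0  # 40 mV excursion
        trace = Trace(y, FS, "mV")
        assert ee.resting_membrane_potential(trace) == pytest.approx(-60.0, abs=0.1)

    def test_noisy_mean_within_standard_error(self):
        rng = np.random.default_rng(5)
        trace = Trace(-55.0 + rng.normal(0, 1.0, int(10 * FS)), FS, "mV")
        assert ee.resting_membrane_potential(trace) == pytest.approx(-55.0, abs=0.05)

    def test_current_trace_rejected(self):
        trace = Trace(np.zeros(100), FS, "pA")
        with pytest.raises(ValueError):
            ee.resting_membrane_potential(trace)


class TestAccessResistanceQC:
    @pytest.mark.parametrize(
        "series, variation, passed",
        [
            ([10, 11, 12], 0.2, True),
            ([10, 13.5], 0.35, False),
            ([10, 10, 10], 0.0, True),
        ],
    )
    def test_variation_rule(self, series, variation, passed):
        qc = ee.access_resistance_qc(series)
        assert qc.max_relative_variation == pytest.approx(variation)
        assert qc.passed is passed

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ee.access_resistance_qc([10.0])
        with pytest.raises(ValueError):
            ee.access_resistance_qc([10.0, -1.0])

    @given(st.floats(0.5, 10.0), st.integers(0, 2**31 - 1))
    def test_scaling_invariance(self, factor, seed):
        rng = np.random.default_rng(seed)
        ra = rng.uniform(8, 20, 5)
        a = ee.access_resistance_qc(ra)
        b = ee.access_resistance_qc(ra * factor)
        assert a.max_relative_variation == pytest.approx(b.max_relative_variation)
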