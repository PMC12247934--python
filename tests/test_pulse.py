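import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import vasomech as vm
from vasomech.errors import AnalysisError, ParameterError


def sinusoid(ptp_amplitude=10.0, mean=500.0, freq=1.0, duration=60.0,
             rate=100.0):
    t = np.arange(int(duration * rate)) / rate
    return t, mean - 0.5 * ptp_amplitude * np.cos(2 * np.pi * freq * t)


class TestDetectPulses:
    def test_sinusoid_count_and_delta(self):
        t, v = sinusoid(ptp_amplitude=10.0)
        s = vm.detect_pulses(t, v)
        assert s.n_peaks == 60
        assert s.mean_delta == pytest.approx(10.0, abs=0.1)

    def test_constant_trace_has_no_peaks(self):
        t = np.arange(300) / 10.0
        s = vm.detect_pulses(t, np.full(300, 500.0))
        assert s.n_peaks == 0

    def test_63_complete_pulses_at_1p06_hz(self, compliant, geom):
        """A one-minute recording at 1.06 pulses/s holds floor(63.6) = 63
        complete pulses when the first cycle starts at t = 0."""
        drive = vm.generate_pulsatile_pressure(
            vm.PulseSpec(80, 120, 1.06 * 60, 60.0, 100.0))
        rec = vm.simulate_recording(compliant, geom, drive)
        s = vm.detect_pulses(rec.time, rec.outer_diameter)
        assert s.n_peaks == 63

    @pytest.mark.parametrize("freq", [0.8, 1.0, 1.3, 2.0])
    def test_count_is_floor_of_cycles(self, freq):
        drive = vm.generate_pulsatile_pressure(
            vm.PulseSpec(80, 120, freq * 60, 30.0, 100.0))
        s = vm.detect_pulses(drive.time, drive.pressure)
        assert s.n_peaks == int(30.0 * freq)

    def test_deltas_nonnegative(self, compliant_recording):
        s = vm.detect_pulses(compliant_recording.time,
                             compliant_recording.outer_diameter)
        assert np.all(s.per_pulse_delta >= 0)
        assert s.n_peaks == s.per_pulse_delta.size


class TestPulseFrequency:
    def test_known_tone(self):
        t, v = sinusoid(freq=2.0)
        assert vm.pulse_frequency(t, v) == pytest.approx(2.0, abs=1 / 60.0)

    def test_ramp_waveform_at_62_bpm(self):
        trace = vm.generate_pulsatile_pressure(
            vm.PulseSpec(80, 120, 62.0, 60.0, 100.0))
        f = vm.pulse_frequency(trace.time, trace.pressure)
        assert round(f, 2) == 1.03

    def test_fundamental_rule_beats_stronger_harmonic(self):
        t = np.arange(6000) / 100.0
        v = 0.6 * np.sin(2 * np.pi * 1.0 * t) + 1.0 * np.sin(2 * np.pi * 2.0 * t)
        assert vm.pulse_frequency(t, v) == pytest.approx(1.0, abs=1 / 60.0)

    def test_constant_signal_rejected(self):
        t = np.arange(600) / 10.0
        with pytest.raises(AnalysisError):
            vm.pulse_frequency(t, np.full(600, 80.0))

    @pytest.mark.parametrize("bpm", [40, 62, 90, 120, 180])
    def test_recovers_generator_beat_rate(self, bpm):
        trace = vm.generate_pulsatile_pressure(
            vm.PulseSpec(80, 120, bpm, 30.0, 200.0))
        f = vm.pulse_frequency(trace.time, trace.pressure)
        assert f == pytest.approx(bpm / 60.0, abs=1 / 30.0)


class TestDynamicCompliance:
    def test_worked_example(self):
        assert vm.dynamic_compliance(550, 500, 120, 80) == pytest.approx(0.0025)

    def test_zero_amplitude(self):
        assert vm.dynamic_compliance(500, 500, 120, 80) == 0.0

    @given(k=st.floats(0.1, 10), shift=st.floats(-50, 50))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_diameter_scale_and_pressure_shift_invariance(self, k, shift):
        base = vm.dynamic_compliance(550, 500, 120, 80)
        assert vm.dynamic_compliance(550 * k, 500 * k, 120, 80) == \
            pytest.approx(base)
        assert vm.dynamic_compliance(550, 500, 120 + shift, 80 + shift) == \
            pytest.approx(base)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            vm.dynamic_compliance(550, 500, 80, 120)
        with pytest.raises(ParameterError):
            vm.dynamic_compliance(550, 0, 120, 80)


class TestRecordingCompliance:
    def test_periodic_recording_zero_spread(self, compliant_recording):
        res = vm.recording_compliance(compliant_recording)
        assert res.n_pulses > 0
        assert res.sd == pytest.approx(0.0, abs=1e-6)

    def test_mean_matches_single_pulse_closed_form(self, compliant_recording):
        res = vm.recording_compliance(compliant_recording)
        d = vm.detect_pulses(compliant_recording.time,
                             compliant_recording.outer_diameter)
        closed = vm.dynamic_compliance(
            float(d.peak_values[0]), d.baseline, res.p_max, res.p_min)
        assert res.mean == pytest.approx(closed, rel=0.01)

    def test_compliant_more_compliant_than_stiff(
            self, compliant_recording, stiff_recording):
        dc1 = vm.recording_compliance(compliant_recording).mean
        dc2 = vm.recording_compliance(stiff_recording).mean
        assert dc1 > dc2


class TestBurstPressure:
    def test_no_rupture_reports_max(self, stiff, geom):
        step = vm.StepSpec(0, 64.37, 1.0, 300, 10.0)
        rec = vm.simulate_burst_experiment(stiff, geom, step, np.inf)
        res = vm.burst_pressure(rec)
        assert not res.ruptured
        assert res.pressure == pytest.approx(5 * 64.37)

    def test_noise_robustness(self, stiff, geom):
        """2 mmHg pressure noise moves the burst estimate by < 3 SD."""
        from vasomech.mechanics import solve_stretch
        from vasomech.waveform import step_levels
        step = vm.StepSpec(0, 64.37, 1.0, 500, 10.0)
        levels = step_levels(step)
        stresses = [vm.circ_stress(stiff, solve_stretch(stiff, geom, P), 1.0)
                    for P in levels]
        sf = 0.5 * (stresses[5] + stresses[6])
        truth = 6 * 64.37
        for seed in range(10):
            rec = vm.simulate_burst_experiment(
                stiff, geom, step, sf, vm.NoiseSpec(0.0, 2.0, seed=seed))
            est = vm.burst_pressure(rec).pressure
            assert abs(est - truth) < 3 * 2.0

    def test_empty_recording_rejected(self):
        rec = vm.MyographyRecording(np.empty(0), np.empty(0),
                                    np.empty(0), np.empty(0))
        with pytest.raises(AnalysisError):
            vm.burst_pressure(rec)


class TestPlateauPressure:
    def test_straight_line_never_plateaus(self):
        P = np.linspace(0, 400, 41)
        assert vm.plateau_pressure(P, 2.0 * P, slope_fraction=0.1) is None

    def test_saturating_curve_closed_form(self):
        P = np.linspace(0, 400, 161)
        OD = 100 * (1 - np.exp(-P / 50.0))
        got = vm.plateau_pressure(P, OD, slope_fraction=0.1)
        assert got == pytest.approx(-50 * np.log(0.1), abs=5.0)

    def test_offset_invariance(self):
        P = np.linspace(0, 400, 161)
        OD = 100 * (1 - np.exp(-P / 50.0))
        assert vm.plateau_pressure(P, OD + 300.0) == vm.plateau_pressure(P, OD)

    def test_flat_curve_has_no_plateau(self):
        P = np.linspace(0, 100, 11)
        assert vm.plateau_pressure(P, np.full(11, 400.0)) is None

    def test_preset_plateau_ordering(self, compliant, stiff, geom):
        """The stiff preset's sweep flattens out well below the compliant
        preset's, mirroring early collagen engagement."""
        P = np.linspace(0, 500, 201)
        plateaus = {}
        for name, p in [("compliant", compliant), ("stiff", stiff)]:
            od = [s.outer_diameter
                  for s in vm.pressure_diameter_curve(p, geom, P)]
            plateaus[name] = vm.plateau_pressure(P, od, slope_fraction=0.1)
        assert plateaus["stiff"] < plateaus["compliant"]
        assert 100 <= plateaus["stiff"] <= 150
        assert 150 <= plateaus["compliant"] <= 250


class TestVasoreactivity:
    def test_constriction_percentages(self):
        dr = vm.DoseResponse([1e-7, 1e-6, 1e-5, 1e-4],
                             [400.0, 380.0, 320.0, 300.0], 400.0,
                             "constrictor")
        # min-max arithmetic: 100 * (400 - D) / (400 - 300)
        assert vm.percent_constriction(dr).tolist() == [0, 20, 80, 100]

    def test_constriction_shift_invariance(self):
        d = np.array([400.0, 380.0, 320.0, 300.0])
        a = vm.percent_constriction(
            vm.DoseResponse([1e-7, 1e-6, 1e-5, 1e-4], d, 400, "constrictor"))
        b = vm.percent_constriction(
            vm.DoseResponse([1e-7, 1e-6, 1e-5, 1e-4], d + 50, 450, "constrictor"))
        assert np.allclose(a, b)

    def test_monotone_input_gives_monotone_output(self):
        dr = vm.simulate_dose_response(400, 0.4, 1e-6, 1.5,
                                       np.logspace(-8, -4, 9), "constrictor")
        pc = vm.percent_constriction(dr)
        assert np.all(np.diff(pc) > 0)
        assert pc.max() == 100.0

    def test_relaxation_percentages(self):
        dr = vm.DoseResponse([1e-7, 1e-6, 1e-5, 1e-4],
                             [300.0, 320.0, 360.0, 400.0], 300.0, "dilator")
        assert vm.percent_relaxation(dr).tolist() == [0, 20, 60, 100]

    def test_single_step_full_dilation(self):
        dr = vm.DoseResponse([1e-6, 1e-4], [300.0, 360.0], 300.0, "dilator")
        assert vm.percent_relaxation(dr).tolist() == [0, 100]

    def test_degenerate_series_rejected(self):
        dr = vm.DoseResponse([1e-6, 1e-4], [300.0, 300.0], 300.0, "constrictor")
        with pytest.raises(AnalysisError):
            vm.percent_constriction(dr)
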