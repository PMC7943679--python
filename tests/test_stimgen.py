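"""Dyad and pulse-train construction: timing arithmetic and waveforms."""

import numpy as np
import pytest

from alfies.stimgen import (
    DyadSpec,
    PulseTrainSpec,
    apply_sinusoidal_am,
    device_dyad_f0,
    inter_pulse_gap,
    interleave_pulse_trains,
    make_biphasic_train,
    make_stepped_dyad,
    make_summed_modulator_train,
    per_train_rate_for_f0,
    pulse_width,
    quantize_midrise,
)
from alfies.waveform import interleave_segments, make_sinusoid


class TestTimingArithmetic:
    """Closed-form stimulus timing derived from the device parameters."""

    def test_device_dyad_fundamental(self):
        # 72 steps of 126.26 us per period
        assert device_dyad_f0(72, 126.26e-6) == pytest.approx(110.0023, abs=5e-5)

    def test_dyad_durations(self):
        spec33 = DyadSpec(
            f1=220.0, f2=330.0, step_duration=126.26e-6,
            steps_per_period=72, duration_periods=33,
        )
        assert spec33.duration * 1e3 == pytest.approx(300.0, abs=0.01)
        spec110 = DyadSpec(
            f1=220.0, f2=330.0, step_duration=126.26e-6,
            steps_per_period=72, duration_periods=110,
        )
        assert spec110.duration == pytest.approx(0.99998, abs=5e-6)

    def test_biphasic_pulse_width_58_us(self):
        assert pulse_width(25e-6, 8e-6) * 1e6 == pytest.approx(58.0)

    def test_composite_rate_and_inter_pulse_gap(self):
        composite = 2 * 2322.0
        assert composite == 4644.0
        gap_us = inter_pulse_gap(composite, 58e-6) * 1e6
        assert gap_us == pytest.approx(157.0, abs=0.5)

    @pytest.mark.parametrize("f0,rate", [(37.0, 1998.0), (40.0, 2160.0), (43.0, 2322.0)])
    def test_per_train_rates_at_54_pulses_per_period(self, f0, rate):
        assert per_train_rate_for_f0(f0, 54) == pytest.approx(rate)


class TestSteppedDyad:
    def test_single_sample_steps_match_ideal_interleave(self):
        # degenerate one-sample step: identical to ideal interleaved sinusoids
        fs = 10000.0
        spec = DyadSpec(f1=80.0, f2=120.0, step_duration=1 / fs, duration_periods=4)
        stepped = make_stepped_dyad(spec, fs)
        ideal = interleave_segments(
            make_sinusoid(80.0, 1.0, spec.duration, fs),
            make_sinusoid(120.0, 1.0, spec.duration, fs),
            1 / fs,
        )
        assert np.allclose(stepped.samples, ideal.samples, atol=1e-12)

    def test_device_dyad_is_periodic_at_f0(self):
        # all spectral energy on multiples of the 110.0023-Hz fundamental
        fs = 5e7
        spec = DyadSpec(
            f1=220.0, f2=330.0, step_duration=126.26e-6,
            steps_per_period=72, duration_periods=2,
        )
        wave = make_stepped_dyad(spec, fs)
        amps = np.abs(np.fft.rfft(wave.samples)) * 2 / len(wave)
        # duration = 2 periods -> F0 grid is the even bins; F1 = 2*F0 on bin 4
        # and F2 = 3*F0 on bin 6 carry the primaries, odd bins must be empty
        # (no energy at F0 itself before any nonlinearity)
        assert amps[4] > 0.1
        assert amps[6] > 0.1
        assert np.abs(amps[1::2]).max() < 1e-9

    def test_quantization_bounds_error_and_overflow(self):
        v = np.linspace(-1, 1, 101)
        q = quantize_midrise(v, 8, 1.0)
        assert np.max(np.abs(q - v)) <= 2.0 / 256  # one LSB
        with pytest.raises(ValueError, match="overflow"):
            quantize_midrise(np.array([1.5]), 8, 1.0)

    def test_superimposed_dyad_with_quantizer_overflows(self):
        # sum of two unit components exceeds the per-component DAC range
        fs = 1e4
        spec = DyadSpec(
            f1=80.0, f2=120.0, step_duration=1e-3, duration_periods=4,
            mode="superimposed", quantization_bits=8,
        )
        with pytest.raises(ValueError, match="overflow"):
            make_stepped_dyad(spec, fs)

    def test_step_duration_off_grid_rejected(self):
        spec = DyadSpec(f1=220.0, f2=330.0, step_duration=126.26e-6,
                        steps_per_period=72)
        with pytest.raises(ValueError, match="integer number of samples"):
            make_stepped_dyad(spec, 1e6)  # 126.26 samples at 1 MHz


class TestBiphasicTrain:
    def test_pulse_count_and_span(self):
        spec = PulseTrainSpec(per_train_rate=2322.0, duration=1.0)
        train = make_biphasic_train(spec, 1e6)
        assert train.n_pulses == 2322
        assert train.pulse_samples == 58  # 25 + 8 + 25 us at 1 MHz

    def test_every_pulse_is_charge_balanced(self):
        spec = PulseTrainSpec(per_train_rate=500.0, duration=0.1)
        train = make_biphasic_train(spec, 1e6)
        for s in train.onset_samples:
            assert np.sum(train.waveform.samples[s : s + train.pulse_samples]) == 0.0
        assert np.sum(train.waveform.samples) == 0.0

    def test_zero_interphase_gap_variant(self):
        spec = PulseTrainSpec(per_train_rate=2322.0, inter_phase_gap=0.0, duration=0.01)
        train = make_biphasic_train(spec, 1e6)
        assert train.pulse_samples == 50  # 25 + 25 us

    def test_cathodic_leading_sign(self):
        spec = PulseTrainSpec(per_train_rate=100.0, duration=0.02)
        train = make_biphasic_train(spec, 1e6)
        s = train.onset_samples[0]
        assert train.waveform.samples[s] == -1.0

    def test_overlapping_pulses_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PulseTrainSpec(per_train_rate=20000.0, duration=0.01)

    def test_onsets_stay_close_to_nominal_times(self):
        spec = PulseTrainSpec(per_train_rate=2322.0, duration=0.5)
        train = make_biphasic_train(spec, 1e6)
        err = train.onset_samples - train.onset_times * 1e6
        assert np.max(np.abs(err)) < 3.0  # noise-shaped rounding, ~2 samples


class TestAmplitudeModulation:
    def _train(self, rate=2322.0, duration=1.0, fs=1e6, **kw):
        spec = PulseTrainSpec(per_train_rate=rate, duration=duration, **kw)
        return make_biphasic_train(spec, fs), spec

    def test_full_depth_envelope_reaches_zero(self):
        train, spec = self._train(mod_freq=80.0, level_low=0.0, level_high=1.0)
        am = apply_sinusoidal_am(train, spec)
        peaks = np.array(
            [np.abs(am.waveform.samples[s : s + am.pulse_samples]).max()
             for s in am.onset_samples]
        )
        assert peaks.min() < 1e-2
        assert peaks.max() == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_envelope_is_identity(self):
        train, spec = self._train(
            duration=0.1, mod_freq=80.0, level_low=0.7, level_high=0.7
        )
        am = apply_sinusoidal_am(train, spec)
        assert np.allclose(am.waveform.samples, 0.7 * train.waveform.samples)

    def test_mean_pulse_amplitude_is_mid_level(self):
        # over an integer number of modulator periods the sinusoid averages out
        train, spec = self._train(mod_freq=80.0, level_low=0.2, level_high=0.8)
        am = apply_sinusoidal_am(train, spec)
        amps = np.array(
            [np.abs(am.waveform.samples[s : s + am.pulse_samples]).max()
             for s in am.onset_samples]
        )
        assert np.mean(amps) == pytest.approx(0.5, abs=1e-9)

    def test_undersampled_modulator_rejected(self):
        train, _ = self._train(duration=0.01)
        with pytest.raises(ValueError, match="undersampled|not below"):
            apply_sinusoidal_am(train, PulseTrainSpec(
                per_train_rate=4644.0, duration=0.01, mod_freq=2000.0))


class TestInterleaveTrains:
    def _am_train(self, mod_freq, rate=2322.0, duration=1.0, fs=1e6):
        spec = PulseTrainSpec(
            per_train_rate=rate, inter_phase_gap=0.0, duration=duration,
            mod_freq=mod_freq, level_low=0.0, level_high=1.0,
        )
        return apply_sinusoidal_am(make_biphasic_train(spec, fs), spec)

    def test_composite_rate_doubles_and_counts_conserve(self):
        a = self._am_train(80.0)
        b = self._am_train(120.0)
        comp = interleave_pulse_trains(a, b)
        assert comp.rate == 4644.0
        assert comp.n_pulses == a.n_pulses + b.n_pulses

    def test_no_sample_receives_both_trains(self):
        a = self._am_train(80.0, duration=0.2)
        b = self._am_train(120.0, duration=0.2)
        comp = interleave_pulse_trains(a, b)
        n = len(a.waveform)
        offset = int(round(1e6 / (2 * 2322.0)))
        m = len(comp.waveform)
        a_active = np.zeros(m, dtype=bool)
        a_active[:n] = a.waveform.samples != 0
        b_active = np.zeros(m, dtype=bool)
        stop = min(m, offset + n)
        b_active[offset:stop] = b.waveform.samples[: stop - offset] != 0
        assert not np.any(a_active & b_active)

    def test_gap_between_composite_pulses(self):
        a = self._am_train(80.0, duration=0.1)
        b = self._am_train(120.0, duration=0.1)
        comp = interleave_pulse_trains(a, b)
        gaps = np.diff(comp.onset_samples) - comp.pulse_samples
        # 157-us inter-pulse gap for 50-us pulses at 4644 pps (zero IPG:
        # period 215.3 us minus 50-us pulse)
        assert np.median(gaps) == pytest.approx(165.0, abs=3.0)

    def test_zero_amplitude_partner_preserves_original(self):
        a = self._am_train(80.0, duration=0.1)
        spec0 = PulseTrainSpec(
            per_train_rate=2322.0, inter_phase_gap=0.0, duration=0.1,
            mod_freq=120.0, level_low=0.0, level_high=0.0,
        )
        zero = apply_sinusoidal_am(make_biphasic_train(spec0, 1e6), spec0)
        comp = interleave_pulse_trains(a, zero)
        assert np.array_equal(
            comp.waveform.samples[: len(a.waveform)], a.waveform.samples
        )

    def test_overlap_rejected_when_rate_too_high(self):
        # composite period at 2x9000 pps is 55.6 us, shorter than the 58-us pulse
        spec = PulseTrainSpec(per_train_rate=9000.0, duration=0.01)
        t = make_biphasic_train(spec, 1e6)
        with pytest.raises(ValueError, match="overlap"):
            interleave_pulse_trains(t, t)


class TestSummedModulatorTrain:
    def test_envelope_is_mean_of_two_envelopes(self):
        fs = 1e6
        spec = PulseTrainSpec(
            per_train_rate=2322.0, inter_phase_gap=0.0, duration=0.1,
            level_low=0.0, level_high=1.0,
        )
        train = make_summed_modulator_train(4644.0, 80.0, 120.0, spec, fs)
        amps = np.array(
            [np.abs(train.waveform.samples[s : s + train.pulse_samples]).max()
             for s in train.onset_samples]
        )
        t = train.onset_times
        m1 = (1 + np.sin(2 * np.pi * 80.0 * t)) / 2
        m2 = (1 + np.sin(2 * np.pi * 120.0 * t)) / 2
        assert np.allclose(amps, (m1 + m2) / 2, atol=1e-9)

    def test_equal_modulators_match_single_modulator_train(self):
        fs = 1e6
        spec = PulseTrainSpec(
            per_train_rate=4644.0, inter_phase_gap=0.0, duration=0.05,
            mod_freq=80.0, level_low=0.0, level_high=1.0,
        )
        summed = make_summed_modulator_train(4644.0, 80.0, 80.0, spec, fs)
        single = apply_sinusoidal_am(make_biphasic_train(spec, fs), spec)
        assert np.allclose(summed.waveform.samples, single.waveform.samples, atol=1e-12)
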