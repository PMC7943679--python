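"""Epoching, drift correction, averaging, F test, group delay, tuning."""

import numpy as np
import pytest

from alfies.analysis import (
    ComponentResult,
    Montage,
    TuningCondition,
    analyze_recording,
    average_epochs,
    build_tuning_curve,
    cut_epochs,
    estimate_group_delay,
    extract_component,
    f_test_component,
    recut_to_integer_periods,
)
from alfies.distortion import compute_spectrum
from alfies.synthrec import Recording, SyntheticEEGSpec, simulate_recording
from alfies.waveform import SampledWaveform

FS = 8192.0


def noise_recording(n_epochs=300, sd=1.0, seed=0, fs=FS):
    rng = np.random.default_rng(seed)
    n = int(n_epochs * fs) + 10
    triggers = (np.arange(n_epochs) * fs).astype(np.int64)
    return Recording(
        data=sd * rng.standard_normal((1, n)),
        channel_names=("derived",),
        sample_rate=fs,
        trigger_indices=triggers,
    )


class TestCutEpochs:
    def test_one_epoch_per_trigger(self):
        rec = noise_recording(n_epochs=300)
        epochs = cut_epochs(rec, 1.0, montage="derived")
        assert epochs.shape == (300, int(FS))

    def test_trailing_incomplete_epoch_dropped(self):
        rec = noise_recording(n_epochs=10)
        rec.trigger_indices = np.append(rec.trigger_indices, rec.n_samples - 5)
        epochs = cut_epochs(rec, 1.0, montage="derived")
        assert epochs.shape[0] == 10

    def test_no_triggers_rejected(self):
        rec = noise_recording(n_epochs=2)
        rec.trigger_indices = np.array([], dtype=np.int64)
        with pytest.raises(ValueError, match="no triggers"):
            cut_epochs(rec, 1.0, montage="derived")


class TestAveraging:
    def test_identical_epochs_average_to_themselves(self):
        epoch = np.sin(np.linspace(0, 10, 512))
        avg = average_epochs(np.tile(epoch, (7, 1)))
        assert np.allclose(avg, epoch)

    def test_white_noise_amplitude_shrinks_as_sqrt_n(self):
        rec = noise_recording(n_epochs=300, sd=1.0, seed=3)
        epochs = cut_epochs(rec, 1.0, montage="derived")
        ratio = epochs.std() / average_epochs(epochs).std()
        assert ratio == pytest.approx(np.sqrt(300), rel=0.2)

    def test_coherent_phase_preserved(self):
        t = np.arange(int(FS)) / FS
        epoch = np.sin(2 * np.pi * 40 * t + 0.8)
        rng = np.random.default_rng(0)
        epochs = epoch + 0.1 * rng.standard_normal((50, epoch.size))
        c = extract_component(average_epochs(epochs), FS, 40.0)
        assert c.phase == pytest.approx(0.8, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_epochs(np.empty((0, 10)))


class TestRecut:
    def _drift_recording(self, ratio, n_epochs=300):
        spec = SyntheticEEGSpec(
            recorder_rate=FS, n_epochs=n_epochs, noise_sd=0.0,
            artefact_amplitudes={"derived": (0.0, 0.0)},
            reference_channel="__none__", ndr_amplitude=1.0,
            ndr_group_delay=0.0, clock_ratio=ratio,
        )
        return simulate_recording(spec, seed=0)

    @staticmethod
    def _adjacent_leakage_db(avg):
        s = compute_spectrum(SampledWaveform(avg, FS, "uV"))
        k = s.bin_index(40.0)
        a = s.amplitudes
        return 20 * np.log10(max(a[k - 1], a[k + 1]) / a[k])

    def test_leakage_suppressed_by_at_least_40_db_at_50_ppm(self):
        rec = self._drift_recording(1 + 50e-6)
        uncorrected = self._adjacent_leakage_db(
            average_epochs(cut_epochs(rec, 1.0, montage="derived"))
        )
        epochs, ratio = recut_to_integer_periods(rec, 1.0, montage="derived")
        corrected = self._adjacent_leakage_db(average_epochs(epochs))
        assert ratio == pytest.approx(1 + 50e-6, abs=1e-7)
        assert corrected <= -60.0
        assert uncorrected - corrected >= 40.0

    def test_identity_when_clocks_agree(self):
        rec = self._drift_recording(1.0, n_epochs=20)
        plain = cut_epochs(rec, 1.0, montage="derived")
        recut, ratio = recut_to_integer_periods(rec, 1.0, montage="derived")
        assert ratio == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(recut, plain, atol=1e-12)

    def test_epoch_count_preserved(self):
        rec = self._drift_recording(1 + 50e-6, n_epochs=50)
        epochs, _ = recut_to_integer_periods(rec, 1.0, montage="derived")
        assert epochs.shape[0] == 50

    def test_jittered_triggers_warn_and_fall_back(self):
        rec = self._drift_recording(1.0, n_epochs=30)
        trig = rec.trigger_indices.copy()
        trig[10] += 4  # jitter beyond the drift model
        rec.trigger_indices = trig
        with pytest.warns(UserWarning, match="jitter"):
            recut_to_integer_periods(rec, 1.0, montage="derived")


class TestFTest:
    def _flat_spectrum(self, target_gain=1.0):
        # build a signal whose bins all carry equal power except the target
        n = 1024
        fs = 1024.0
        rng = np.random.default_rng(1)
        freqs = np.arange(1, 512)
        phases = rng.uniform(0, 2 * np.pi, freqs.size)
        t = np.arange(n) / fs
        x = np.zeros(n)
        for f, ph in zip(freqs, phases):
            gain = target_gain if f == 100 else 1.0
            x += gain * np.cos(2 * np.pi * f * t + ph)
        return compute_spectrum(SampledWaveform(x, fs, "uV"))

    def test_equal_power_bins_give_ratio_one(self):
        s = self._flat_spectrum()
        f_ratio, significant, _ = f_test_component(s, 100.0)
        assert f_ratio == pytest.approx(1.0, rel=1e-9)
        assert not significant

    def test_20_db_component_gives_ratio_100(self):
        s = self._flat_spectrum(target_gain=10.0)
        f_ratio, significant, _ = f_test_component(s, 100.0)
        assert f_ratio == pytest.approx(100.0, rel=1e-9)
        assert significant

    def test_false_positive_rate_below_one_percent(self):
        rng = np.random.default_rng(7)
        n = 1024
        hits = 0
        draws = 2000
        for _ in range(draws):
            s = compute_spectrum(
                SampledWaveform(rng.standard_normal(n), 1024.0, "uV")
            )
            _, sig, _ = f_test_component(s, 100.0)
            hits += sig
        assert hits / draws <= 0.01

    def test_excluded_bins_are_skipped(self):
        s = self._flat_spectrum()
        _, _, flanks = f_test_component(s, 100.0, exclude_freqs=(98.0, 103.0))
        assert 98 not in flanks and 103 not in flanks
        assert flanks.size == 12

    def test_too_few_flanking_bins_rejected(self):
        s = compute_spectrum(SampledWaveform(np.ones(16), 16.0, "uV"))
        with pytest.raises(ValueError, match="flanking"):
            f_test_component(s, 4.0)

    def test_scale_invariance(self):
        rec_small = noise_recording(n_epochs=20, sd=1.0, seed=5)
        rec_big = Recording(
            data=rec_small.data * 1000.0,
            channel_names=rec_small.channel_names,
            sample_rate=rec_small.sample_rate,
            trigger_indices=rec_small.trigger_indices,
        )
        c1 = analyze_recording(rec_small, 40.0, 80.0, 120.0, montage="derived")
        c2 = analyze_recording(rec_big, 40.0, 80.0, 120.0, montage="derived")
        assert c1.components[40.0].f_ratio == pytest.approx(
            c2.components[40.0].f_ratio, rel=1e-9
        )


class TestGroupDelay:
    @staticmethod
    def wrap(p):
        return (p + np.pi) % (2 * np.pi) - np.pi

    @pytest.mark.parametrize("tau_ms", [0.0, 44.0, 45.0])
    def test_exact_recovery_of_encoded_delay(self, tau_ms):
        freqs = np.array([37.0, 40.0, 43.0])
        phases = self.wrap(-2 * np.pi * freqs * tau_ms / 1000.0)
        gd = estimate_group_delay(freqs, phases)
        assert gd.delay_ms == pytest.approx(tau_ms, abs=1e-9)
        assert not gd.ambiguous

    def test_two_point_estimate_equals_closed_form(self):
        freqs = np.array([37.0, 43.0])
        tau = 0.0315
        phases = self.wrap(-2 * np.pi * freqs * tau)
        gd = estimate_group_delay(freqs, phases)
        d = self.wrap(phases[1] - phases[0]) - 2 * np.pi * np.round(
            (self.wrap(phases[1] - phases[0]) + 2 * np.pi * 6.0 * tau) / (2 * np.pi)
        )
        closed = -d / (2 * np.pi * 6.0) * 1000.0
        assert gd.delay_ms == pytest.approx(closed, abs=1e-9)
        assert gd.delay_ms == pytest.approx(tau * 1000, abs=1e-9)

    @pytest.mark.parametrize("tau_ms", [0.0, 45.0])
    def test_von_mises_noise_mean_recovery_within_2_ms(self, tau_ms):
        rng = np.random.default_rng(2024)
        freqs = np.array([37.0, 40.0, 43.0])
        estimates = []
        for _ in range(100):
            phases = self.wrap(
                -2 * np.pi * freqs * tau_ms / 1000.0 + rng.vonmises(0.0, 50.0, 3)
            )
            estimates.append(estimate_group_delay(freqs, phases).delay_ms)
        assert np.mean(estimates) == pytest.approx(tau_ms, abs=2.0)

    def test_delay_outside_search_range_not_invented(self):
        # a 200-ms delay aliases; the estimator reports a candidate list
        freqs = np.array([37.0, 40.0, 43.0])
        phases = self.wrap(-2 * np.pi * freqs * 0.045)
        gd = estimate_group_delay(freqs, phases, delay_range_ms=(0.0, 100.0))
        assert len(gd.candidate_delays_ms) >= 1

    def test_single_frequency_rejected(self):
        with pytest.raises(ValueError):
            estimate_group_delay([40.0], [0.1])


def _component(amp, floor=0.01, significant=True):
    return ComponentResult(
        frequency=43.0, amplitude=amp, phase=0.0,
        f_ratio=100.0 if significant else 1.0,
        significant=significant, noise_floor=floor,
    )


class TestTuningCurve:
    def test_families_are_separated_and_ordered(self):
        conditions = [
            TuningCondition(20, 20, _component(0.15)),
            TuningCondition(19, 19, _component(0.15)),
            TuningCondition(20, 19, _component(0.10)),
            TuningCondition(20, 8, _component(0.011, significant=False)),
        ]
        curve = build_tuning_curve(conditions)
        assert curve.f2_electrodes == (20, 19, 8)
        assert curve.same_electrode_db[0] == pytest.approx(
            20 * np.log10(0.15)
        )
        assert curve.same_electrode_db[2] is None  # explicit gap
        assert curve.flagged_different[2]  # at the noise floor

    def test_flat_same_electrode_curve(self):
        conditions = [
            TuningCondition(e, e, _component(0.15)) for e in (20, 19, 14, 8)
        ]
        curve = build_tuning_curve(conditions)
        vals = [v for v in curve.same_electrode_db if v is not None]
        assert np.ptp(vals) < 1e-12


class TestMontage:
    def test_default_montage_arithmetic(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, 100))
        rec = Recording(
            data=data, channel_names=("ipsi", "contra", "back", "cz"),
            sample_rate=100.0, trigger_indices=np.array([0]),
        )
        out = Montage().derive(rec)
        assert np.allclose(out, data[:3].mean(axis=0) - data[3])

    def test_missing_channel_reported(self):
        rec = Recording(
            data=np.zeros((1, 10)), channel_names=("a",),
            sample_rate=10.0, trigger_indices=np.array([0]),
        )
        with pytest.raises(KeyError, match="no channel"):
            Montage().derive(rec)
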