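import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from soundseek.stimulus import (
    FIXED_PRESET,
    VARIABLE_RANGES,
    BurstTrain,
    StimulusParams,
    apply_calibration,
    fit_calibration,
    make_train,
    measure_spectrum_db,
    render_stream,
    sample_intervals,
    sample_trial_params,
    synth_burst,
)


class TestSampleIntervals:
    def test_zero_irregularity_is_perfectly_periodic(self):
        intervals = sample_intervals(4, 0, 1, rng=0)
        assert np.allclose(intervals, 0.25)
        assert len(intervals) == 4

    def test_fixed_preset_moments(self):
        # Large-sample mean must hit 1/rate and SD the irregularity;
        # the oracle for the moment mapping is shape*scale = mean and
        # shape*scale^2 = variance of the gamma law.
        intervals = sample_intervals(4, 31, 30_000, rng=42)
        n = len(intervals)
        assert n > 100_000
        se_mean = intervals.std(ddof=1) / np.sqrt(n)
        assert abs(intervals.mean() - 0.250) < 3 * se_mean
        sd_ms = intervals.std(ddof=1) * 1000.0
        # SE of the sample SD from the sample's own fourth moment.
        m4 = np.mean((intervals - intervals.mean()) ** 4)
        var = intervals.var(ddof=1)
        se_sd = np.sqrt(max(m4 - var**2, 0) / n) / (2 * np.sqrt(var)) * 1000
        assert abs(sd_ms - 31.0) < 3 * se_sd

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(rate=st.floats(0.5, 20.0), irregularity=st.floats(0.1, 120.0))
    def test_moment_mapping_property(self, rate, irregularity):
        duration = max(4000.0 / rate, 500.0)
        intervals = sample_intervals(rate, irregularity, duration, rng=7)
        n = len(intervals)
        se_mean = intervals.std(ddof=1) / np.sqrt(n)
        assert abs(intervals.mean() - 1.0 / rate) < 4 * se_mean
        assert np.all(intervals > 0)

    def test_cumulative_sum_within_duration(self):
        intervals = sample_intervals(4, 31, 10, rng=3)
        assert intervals.sum() <= 10

    @pytest.mark.parametrize("kwargs", [
        {"rate": 0, "irregularity": 31, "duration": 1},
        {"rate": -1, "irregularity": 31, "duration": 1},
        {"rate": 4, "irregularity": -1, "duration": 1},
        {"rate": 4, "irregularity": 31, "duration": 0},
    ])
    def test_parameter_errors(self, kwargs):
        with pytest.raises(ValueError):
            sample_intervals(rng=0, **kwargs)


class TestSynthBurst:
    def test_fixed_preset_length_and_band_concentration(self):
        wave = synth_burst(FIXED_PRESET, 192_000, rng=0)
        assert len(wave) == 1920
        f, p = signal.periodogram(wave, fs=192_000)
        inband = p[(f >= 8500) & (f <= 11500)].sum() / p.sum()
        assert inband >= 0.90

    def test_level_sets_rms(self):
        wave = synth_burst(FIXED_PRESET, 192_000, rng=0)
        target = 10 ** ((70 - 94) / 20) / np.sqrt(2)
        assert np.sqrt(np.mean(wave**2)) == pytest.approx(target, rel=1e-6)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            StimulusParams(burst_duration=0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            synth_burst(FIXED_PRESET, 20_000, rng=0)

    def test_same_seed_bit_identical(self):
        a = synth_burst(FIXED_PRESET, 192_000, rng=11)
        b = synth_burst(FIXED_PRESET, 192_000, rng=11)
        assert np.array_equal(a, b)


class TestRenderStream:
    def test_empty_train_is_silence(self):
        train = BurstTrain(onsets=np.array([]), params=FIXED_PRESET,
                           duration=1.0)
        wave = render_stream(train, 48_000)
        assert wave.shape == (48_000,)
        assert np.all(wave == 0)

    def test_single_onset_at_zero_is_padded_burst(self):
        train = BurstTrain(onsets=np.array([0.0]), params=FIXED_PRESET,
                           duration=0.5)
        wave = render_stream(train, 48_000, rng=5)
        burst = synth_burst(FIXED_PRESET, 48_000, rng=np.random.default_rng(5))
        n = len(burst)
        assert np.array_equal(wave[:n], burst)
        assert np.all(wave[n:] == 0)

    def test_burst_count_near_rate_times_duration(self):
        # Oracle: onsets of a 4 Hz train over 10 s number 40 +/- renewal
        # sampling error.
        counts = [len(make_train(FIXED_PRESET, 10.0, rng=s).onsets)
                  for s in range(30)]
        assert abs(np.mean(counts) - 40) < 3 * np.std(counts) / np.sqrt(30)

    def test_overlapping_bursts_warn_and_sum(self):
        train = BurstTrain(onsets=np.array([0.0, 0.005]),
                           params=FIXED_PRESET, duration=0.1)
        with pytest.warns(UserWarning, match="overlap"):
            wave = render_stream(train, 48_000, rng=0)
        assert len(wave) == 4800

    def test_invalid_onsets_rejected(self):
        with pytest.raises(ValueError):
            BurstTrain(onsets=np.array([0.2, 0.1]), params=FIXED_PRESET,
                       duration=1.0)
        with pytest.raises(ValueError):
            BurstTrain(onsets=np.array([0.5, 1.5]), params=FIXED_PRESET,
                       duration=1.0)


class TestSampleTrialParams:
    def test_fixed_mode_returns_preset(self):
        params = sample_trial_params("fixed", rng=0)
        assert params == StimulusParams(10.0, 3.0, 10.0, 70.0, 4.0, 31.0)

    def test_variable_draws_inside_ranges(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            p = sample_trial_params("variable", rng)
            for name, (lo, hi) in VARIABLE_RANGES.items():
                assert lo <= getattr(p, name) <= hi

    def test_same_seed_identical_sequence(self):
        seq1 = [sample_trial_params("variable", np.random.default_rng(9))
                for _ in range(5)]
        seq2 = [sample_trial_params("variable", np.random.default_rng(9))
                for _ in range(5)]
        assert seq1 == seq2

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            sample_trial_params("adaptive", rng=0)


class TestCalibration:
    def test_flat_spectrum_gives_zero_curve(self):
        freqs = np.linspace(5, 20, 31)
        curve = fit_calibration(freqs, np.full(31, 60.0))
        assert np.allclose(curve.gain_db, 0.0)

    def test_notch_is_mirrored(self):
        freqs = np.linspace(5, 20, 31)
        level = np.full(31, 60.0)
        i10k = np.argmin(np.abs(freqs - 10))
        level[i10k] -= 6.0
        curve = fit_calibration(freqs, level, target_db=60.0)
        assert curve.gain_db[i10k] == pytest.approx(6.0)
        mask = np.ones(31, bool)
        mask[i10k] = False
        assert np.allclose(curve.gain_db[mask], 0.0)

    def test_round_trip_flattens_two_pole_response(self):
        # Oracle: forward-filter a flat source by a known 2-pole
        # response, fit the correction from that response, and check the
        # deterministic combined transfer function is flat to <= 1 dB
        # over the behavioral band.
        fs = 96_000
        sos = signal.butter(2, 25_000, btype="lowpass", fs=fs, output="sos")
        grid_khz = np.linspace(5, 20, 61)
        _, h = signal.sosfreqz(sos, worN=grid_khz * 1000, fs=fs)
        measured_db = 60.0 + 20 * np.log10(np.abs(h))
        curve = fit_calibration(grid_khz, measured_db)

        eval_hz = np.linspace(5000, 20000, 301)
        fir = signal.firwin2(
            511,
            np.concatenate([[0], grid_khz * 1000, [fs / 2]]),
            10 ** (np.concatenate([[curve.gain_db[0]], curve.gain_db,
                                   [curve.gain_db[-1]]]) / 20),
            fs=fs,
        )
        _, h_sys = signal.sosfreqz(sos, worN=eval_hz, fs=fs)
        _, h_fir = signal.freqz(fir, worN=eval_hz, fs=fs)
        combined_db = 20 * np.log10(np.abs(h_sys * h_fir))
        assert combined_db.max() - combined_db.min() <= 1.0

    def test_apply_calibration_boosts_notched_band(self):
        # Equalizing a white-noise waveform with a +6 dB correction at
        # 10 kHz raises the measured level there by ~6 dB.
        fs = 96_000
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(fs * 4)
        grid = np.linspace(5, 20, 31)
        gain = np.zeros(31)
        gain[np.argmin(np.abs(grid - 10))] = 6.0
        # Smooth the single-point notch so the FIR can realize it.
        gain = np.convolve(gain, np.ones(5) / 5, mode="same") * 5
        curve = fit_calibration(grid, -gain, target_db=0.0)
        out = apply_calibration(noise, curve, fs)
        before = measure_spectrum_db(noise, fs, [10.0])[0]
        after = measure_spectrum_db(out, fs, [10.0])[0]
        assert after - before == pytest.approx(6.0, abs=1.5)

    def test_non_finite_spectrum_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([5, 10], [60.0, -np.inf])
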