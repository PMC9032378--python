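"""Unit and property tests of the CM extraction chain."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ecochg.extraction import (
    ExtractionConfig,
    RawBuffer,
    difference_average,
    extract_point,
    extract_trace,
    noise_floor,
    response_magnitude_phase,
    spectrum,
)
from ecochg.stimulus import SAMPLE_RATE_HZ, StimulusSpec
from ecochg.synthetic import LatentTrajectory, noise_sigma_for_floor, synthesize_buffers

FS = SAMPLE_RATE_HZ
N_WIN = 464


def brute_force_dft(x):
    """O(N^2) reference DFT with the same single-sided amplitude scaling."""
    n = len(x)
    ks = np.arange(n // 2 + 1)
    out = np.array(
        [np.sum(x * np.exp(-2j * np.pi * k * np.arange(n) / n)) for k in ks]
    )
    scale = np.full(len(ks), 2.0 / n)
    scale[0] = 1.0 / n
    if n % 2 == 0:
        scale[-1] = 1.0 / n
    return out * scale


def on_bin_tone(amplitude_uv, frequency_hz=500.0, phase_deg=0.0, n=N_WIN):
    t = np.arange(n) / FS
    return amplitude_uv * np.cos(2 * np.pi * frequency_hz * t + np.radians(phase_deg))


class TestDifferenceAverage:
    def test_pure_cm_recovered(self):
        s = on_bin_tone(50.0)
        pair = (
            RawBuffer(s, "condensation", 0.0),
            RawBuffer(-s, "rarefaction", 0.0625),
        )
        np.testing.assert_array_equal(difference_average(pair), s)

    def test_polarity_invariant_component_cancels_exactly(self):
        nuisance = np.sin(np.linspace(0, 40, N_WIN)) * np.exp(-np.linspace(0, 5, N_WIN))
        pair = (
            RawBuffer(nuisance, "condensation", 0.0),
            RawBuffer(nuisance, "rarefaction", 0.0625),
        )
        assert np.all(difference_average(pair) == 0.0)

    def test_nuisance_suppressed_cm_preserved(self):
        cm = on_bin_tone(50.0)
        t = np.arange(N_WIN) / FS
        nuisance = 10.0 * np.exp(-t / 0.005) * np.sin(2 * np.pi * 1000 * t)
        pair = (
            RawBuffer(cm + nuisance, "condensation", 0.0),
            RawBuffer(-cm + nuisance, "rarefaction", 0.0625),
        )
        epoch = difference_average(pair)
        amp, _ = response_magnitude_phase(spectrum(epoch), 500.0)
        assert amp == pytest.approx(50.0, abs=1e-9)
        # residual nuisance energy at its own frequency is gone entirely
        nuis_amp = np.abs(spectrum(epoch).values[spectrum(epoch).bin_index(1000.0)])
        assert nuis_amp < 50.0 * 10 ** (-60 / 20)

    def test_same_polarity_rejected(self):
        s = on_bin_tone(1.0)
        with pytest.raises(ValueError, match="opposite"):
            difference_average((RawBuffer(s, "condensation", 0.0), RawBuffer(s, "condensation", 0.1)))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            difference_average(
                (RawBuffer(np.zeros(10), "condensation", 0.0), RawBuffer(np.zeros(9), "rarefaction", 0.1))
            )


class TestSpectrum:
    def test_on_bin_sinusoid_magnitude(self):
        spec = spectrum(on_bin_tone(50.0))
        assert spec.bin_hz == pytest.approx(20.0)
        assert spec.magnitudes[25] == pytest.approx(50.0, abs=1e-9)

    def test_zero_input_zero_spectrum(self):
        assert np.all(spectrum(np.zeros(N_WIN)).magnitudes == 0.0)

    def test_central_window_is_used(self):
        epoch = np.zeros(512)
        epoch[24:488] = on_bin_tone(7.0)
        spec = spectrum(epoch, window_samples=464)
        assert spec.magnitudes[25] == pytest.approx(7.0, abs=1e-9)

    def test_short_epoch_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            spectrum(np.zeros(100), window_samples=464)

    @given(
        arrays(
            np.float64,
            st.sampled_from([16, 64, 101, 464, 512]),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_matches_brute_force_dft(self, x):
        got = spectrum(x).values
        want = brute_force_dft(x)
        scale = max(np.max(np.abs(want)), 1.0)
        np.testing.assert_allclose(got, want, atol=1e-9 * scale)


class TestMagnitudePhase:
    def test_zero_phase_cosine(self):
        _, phase = response_magnitude_phase(spectrum(on_bin_tone(10.0)), 500.0)
        assert phase == pytest.approx(0.0, abs=1e-9)

    def test_quarter_period_delay_gives_minus_90(self):
        t = np.arange(N_WIN) / FS
        delayed = 10.0 * np.cos(2 * np.pi * 500.0 * (t - 1 / 2000.0))
        _, phase = response_magnitude_phase(spectrum(delayed), 500.0)
        assert phase == pytest.approx(-90.0, abs=1e-6)

    @pytest.mark.parametrize("phase_deg", [-179.0, -90.0, 0.0, 45.0, 180.0])
    def test_amplitude_invariant_to_phase(self, phase_deg):
        amp, got = response_magnitude_phase(spectrum(on_bin_tone(12.0, phase_deg=phase_deg)), 500.0)
        assert amp == pytest.approx(12.0, abs=1e-9)
        assert got == pytest.approx(phase_deg, abs=1e-6)
        assert -180.0 < got <= 180.0


class TestNoiseFloor:
    def test_uniform_surrounding_bins(self):
        # tones exactly on the six default noise bins, 1 uV each
        x = sum(on_bin_tone(1.0, frequency_hz=20.0 * k) for k in (21, 22, 23, 27, 28, 29))
        assert noise_floor(spectrum(x), 500.0) == pytest.approx(1.0, abs=1e-9)

    def test_pure_tone_has_no_leakage_floor(self):
        assert noise_floor(spectrum(on_bin_tone(50.0)), 500.0) <= 1e-9

    def test_insufficient_bins_rejected(self):
        with pytest.raises(ValueError, match="bins"):
            noise_floor(spectrum(on_bin_tone(1.0)), 500.0, noise_bins_each_side=30, guard_bins=0)
        with pytest.raises(ValueError, match="bins"):
            noise_floor(spectrum(np.zeros(N_WIN)), 40.0)

    def test_white_noise_floor_matches_rayleigh_mean(self):
        # per-sample sigma -> Rayleigh mean sigma*sqrt(pi/N) per bin
        sigma = 3.0
        floors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            floors.append(noise_floor(spectrum(rng.normal(0, sigma, N_WIN)), 500.0))
        expected = sigma * np.sqrt(np.pi / N_WIN)
        assert np.mean(floors) == pytest.approx(expected, rel=0.2)


def constant_buffers(amplitude_uv, noise_floor_uv, seed, duration_s=60.0, phase_deg=0.0):
    traj = LatentTrajectory(
        np.array([0.0, duration_s]),
        np.full(2, float(amplitude_uv)),
        np.full(2, float(phase_deg)),
    )
    return synthesize_buffers(traj, StimulusSpec(), noise_floor_uv, seed)


class TestStoppingRule:
    def test_strong_signal_stops_after_one_pair(self):
        point = extract_point(constant_buffers(50.0, 0.0, 1))
        assert point.n_averages == 1
        assert point.above_floor

    def test_noise_only_runs_to_max_averages(self):
        bufs = constant_buffers(0.0, 1.0, 2)
        point = extract_point(bufs)
        assert point.n_averages == 40
        assert point.snr_db < 12.0

    def test_six_db_single_pair_snr_stops_near_four_averages(self):
        amp = 10 ** (6 / 20)  # 6 dB above a 1 uV floor
        counts = [
            extract_point(constant_buffers(amp, 1.0, seed, duration_s=30.0)).n_averages
            for seed in range(100)
        ]
        assert 3.0 <= np.mean(counts) <= 5.0
        assert max(counts) <= 40

    def test_averaging_gain_scales_floor_as_inverse_sqrt_n(self):
        # force exactly n averages with an unreachable SNR target
        def mean_floor(n_avg, n_runs=200):
            floors = []
            config = ExtractionConfig(snr_stop_db=1e6, max_averages=n_avg)
            for seed in range(n_runs):
                bufs = constant_buffers(0.0, 1.0, 1000 + seed, duration_s=n_avg * 0.125 + 1)
                floors.append(extract_point(bufs, config).noise_floor_uv)
            return np.mean(floors)

        ratio = mean_floor(1) / mean_floor(16)
        assert ratio == pytest.approx(4.0, rel=0.1)


class TestTraces:
    def test_point_rate_is_eight_per_second_for_strong_signal(self):
        trace = extract_trace(constant_buffers(50.0, 0.0, 3, duration_s=10.0))
        rate = len(trace.points) / 10.0
        assert rate == pytest.approx(8.0, rel=0.05)
        assert np.all(np.diff(trace.times) > 0)

    def test_empty_stream_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_trace([])

    def test_mid_pair_exhaustion_rejected(self):
        bufs = constant_buffers(50.0, 0.0, 4, duration_s=2.0)
        with pytest.raises(ValueError, match="mid-pair"):
            extract_trace(bufs[:-1])

    def test_noiseless_recovery_within_tenth_db_and_one_degree(self):
        times = np.arange(0.0, 30.1, 0.125)
        amp = 40.0 * 10 ** (np.linspace(-6, 0, len(times)) / 20)
        phase = np.linspace(0.0, 90.0, len(times))
        traj = LatentTrajectory(times, amp, phase)
        bufs = synthesize_buffers(traj, StimulusSpec(), 0.0, 5)
        trace = extract_trace(bufs)
        want_amp = np.interp(trace.times, times, amp)
        want_phase = np.interp(trace.times, times, phase)
        err_db = 20 * np.log10(trace.amplitudes_uv / want_amp)
        assert np.max(np.abs(err_db)) < 0.1
        assert np.max(np.abs(trace.phases_deg - want_phase)) < 1.0


def test_trace_dataframe_round_trip():
    trace = extract_trace(constant_buffers(50.0, 0.0, 6, duration_s=3.0), subject_id="S001")
    df = trace.to_dataframe()
    from ecochg.extraction import InsertionTrace

    back = InsertionTrace.from_dataframe(df)
    assert back.subject_id == "S001"
    np.testing.assert_allclose(back.amplitudes_uv, trace.amplitudes_uv)
    np.testing.assert_allclose(back.times, trace.times)


def test_noise_sigma_calibration_single_pair_floor():
    floors = []
    for seed in range(60):
        bufs = constant_buffers(0.0, 2.5, 100 + seed, duration_s=1.0)
        epoch = difference_average((bufs[0], bufs[1]))
        floors.append(noise_floor(spectrum(epoch, 464), 500.0))
    assert np.mean(floors) == pytest.approx(2.5, rel=0.2)
    assert noise_sigma_for_floor(1.0) == pytest.approx(np.sqrt(2 * 464 / np.pi))
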