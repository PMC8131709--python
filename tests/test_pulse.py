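"""Chirp synthesis, fast ramping, pulse compression, and FRC extraction."""

import numpy as np
import pytest
from scipy.signal import find_peaks, hilbert

from echospecies.pulse import (
    FRC,
    AliasingError,
    ChirpConfig,
    EchoTrace,
    apply_fast_ramp,
    compressed_peak_delay,
    default_frc_grid,
    extract_frc,
    make_chirp,
    pulse_compress,
)
from echospecies.simulate import simulate_echo


def instantaneous_frequency(signal, sample_rate):
    """Phase-difference oracle: d(phase)/dt of the analytic signal."""
    phase = np.unwrap(np.angle(hilbert(signal)))
    return np.diff(phase) * sample_rate / (2 * np.pi)


class TestMakeChirp:
    def test_length_matches_duration(self, chirp_config):
        assert make_chirp(chirp_config).size == 768  # 0.512 ms x 1.5 MHz

    def test_sweep_is_linear_between_band_edges(self, chirp_config):
        chirp = make_chirp(chirp_config)
        inst = instantaneous_frequency(chirp, chirp_config.sample_rate)
        n = inst.size
        mid = inst[n // 2 - 5 : n // 2 + 5].mean()
        assert mid == pytest.approx(130e3, rel=0.01)  # midpoint of 90-170
        early = inst[50:60].mean()
        late = inst[-60:-50].mean()
        assert early < mid < late

    def test_degenerate_band_gives_pure_tone(self):
        config = ChirpConfig(f_start=120e3, f_end=120e3)
        inst = instantaneous_frequency(make_chirp(config), config.sample_rate)
        assert np.median(inst) == pytest.approx(120e3, rel=0.01)
        assert np.std(inst[100:-100]) < 0.05 * 120e3

    def test_subnyquist_sample_rate_rejected(self):
        with pytest.raises(AliasingError):
            ChirpConfig(sample_rate=300e3)


class TestFastRamp:
    def test_interior_unchanged_and_energy_reduced(self, chirp_config):
        chirp = make_chirp(chirp_config)
        ramped = apply_fast_ramp(chirp, chirp_config)
        n_taper = int(round(2 / 120e3 * chirp_config.sample_rate))
        assert np.array_equal(ramped[n_taper:-n_taper], chirp[n_taper:-n_taper])
        assert np.sum(ramped**2) <= np.sum(chirp**2)

    def test_taper_spans_two_nominal_wavelengths(self, chirp_config):
        # 2 / 120 kHz = 16.67 us per end
        n_taper = int(round(2 / 120e3 * chirp_config.sample_rate))
        assert n_taper / chirp_config.sample_rate == pytest.approx(16.67e-6, rel=0.01)

    def test_too_short_signal_rejected(self, chirp_config):
        with pytest.raises(ValueError, match="too short"):
            apply_fast_ramp(np.ones(10), chirp_config)


class TestPulseCompression:
    def test_autocorrelation_peaks_at_zero_lag(self, chirp_config):
        chirp = make_chirp(chirp_config)
        echo = EchoTrace(chirp, chirp_config.sample_rate)
        compressed, lags = pulse_compress(echo, chirp)
        assert lags[np.argmax(np.abs(compressed))] == 0.0
        assert np.max(compressed) == pytest.approx(1.0)  # energy-normalized

    def test_mainlobe_width_is_reciprocal_bandwidth(self, chirp_config):
        chirp = make_chirp(chirp_config)
        compressed, _ = pulse_compress(EchoTrace(chirp, chirp_config.sample_rate), chirp)
        envelope = np.abs(hilbert(compressed))
        envelope /= envelope.max()
        above = np.where(envelope >= 10 ** (-3 / 20))[0]
        width = (above[-1] - above[0]) / chirp_config.sample_rate
        assert width == pytest.approx(1 / 80e3, rel=0.20)

    def test_side_lobes_present_but_suppressed(self, chirp_config):
        chirp = make_chirp(chirp_config)
        compressed, _ = pulse_compress(EchoTrace(chirp, chirp_config.sample_rate), chirp)
        envelope = np.abs(hilbert(compressed))
        envelope /= envelope.max()
        peaks, _ = find_peaks(envelope)
        main = int(np.argmax(envelope))
        side = [envelope[p] for p in peaks if abs(p - main) > 5 and envelope[p] > 1e-6]
        assert side, "side lobes should exist"
        assert 20 * np.log10(max(side)) <= -13.0

    def test_zero_energy_replica_rejected(self, chirp_config):
        echo = EchoTrace(np.ones(100), chirp_config.sample_rate)
        with pytest.raises(ValueError, match="zero energy"):
            pulse_compress(echo, np.zeros(50))

    def test_two_point_targets_resolved(self, chirp_config, replica):
        # two all-pass targets 5 cm apart in range -> two envelope peaks
        e1 = simulate_echo(chirp_config, np.ones(656), range_m=3.00)
        e2 = simulate_echo(chirp_config, np.ones(656), range_m=3.05)
        n = max(e1.samples.size, e2.samples.size)
        summed = np.zeros(n)
        summed[: e1.samples.size] += e1.samples
        summed[: e2.samples.size] += e2.samples
        compressed, lags = pulse_compress(
            EchoTrace(summed, chirp_config.sample_rate), replica
        )
        envelope = np.abs(hilbert(compressed))
        envelope /= envelope.max()
        peaks, _ = find_peaks(envelope, height=0.3, distance=20)
        expected = [2 * 3.00 / 1450.0, 2 * 3.05 / 1450.0]
        found = lags[peaks]
        for t in expected:
            assert np.min(np.abs(found - t)) < 10e-6


class TestEchoDelay:
    def test_two_way_travel_time(self, chirp_config, replica):
        echo = simulate_echo(chirp_config, np.ones(656), range_m=3.0)
        delay = compressed_peak_delay(echo, replica)
        assert delay == pytest.approx(2 * 3.0 / 1450.0, abs=2e-6)  # ~4.138 ms


class TestExtractFrc:
    def test_all_pass_target_gives_flat_unit_curve(self, chirp_config, replica):
        echo = simulate_echo(chirp_config, np.ones(656), range_m=2.5)
        frc = extract_frc(echo, replica)
        assert frc.amplitudes.max() == 1.0
        assert frc.amplitudes.min() > 0.97

    def test_scale_invariance(self, chirp_config, replica, grid):
        echo = simulate_echo(chirp_config, np.linspace(1.0, 0.3, 656), range_m=2.5)
        frc = extract_frc(echo, replica)
        scaled = EchoTrace(10.0 * echo.samples, echo.sample_rate)
        frc10 = extract_frc(scaled, replica)
        np.testing.assert_allclose(frc10.amplitudes, frc.amplitudes, rtol=1e-9)

    def test_gaussian_notch_located(self, chirp_config, replica, grid):
        response = 1.0 - 0.9 * np.exp(-0.5 * ((grid - 150e3) / 2e3) ** 2)
        echo = simulate_echo(chirp_config, response, range_m=2.5)
        frc = extract_frc(echo, replica)
        f_min = grid[np.argmin(frc.amplitudes)]
        assert abs(f_min - 150e3) <= 2e3

    def test_round_trip_recovers_spectrum(self, chirp_config, replica, grid):
        from echospecies.simulate import smooth_gaussian_field

        rng = np.random.default_rng(0)
        field = smooth_gaussian_field(rng, grid, 8e3)
        response = 0.55 + 0.35 * np.tanh(field / 1.5)
        echo = simulate_echo(chirp_config, response, range_m=3.3)
        frc = extract_frc(echo, replica)
        target = response / response.max()
        rms = np.sqrt(np.mean((frc.amplitudes - target) ** 2))
        assert rms < 0.05

    def test_grid_contract(self, grid):
        assert grid.size == 656
        assert grid[0] == 90e3 and grid[-1] == 170e3

    def test_window_outside_trace_rejected(self, chirp_config, replica):
        echo = simulate_echo(chirp_config, np.ones(656), range_m=2.5)
        with pytest.raises(ValueError, match="outside the trace"):
            extract_frc(echo, replica, window=(1.0, 0.6e-3))

    def test_frc_invariants_enforced(self, grid):
        with pytest.raises(ValueError, match="656"):
            FRC(np.ones(100))
        bad = np.ones(656)
        bad[3] = -0.1
        with pytest.raises(ValueError, match="positive"):
            FRC(bad)
        with pytest.raises(ValueError, match="normalized"):
            FRC(np.full(656, 0.5))
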