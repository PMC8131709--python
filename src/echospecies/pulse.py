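"""Wideband pulse synthesis, matched filtering, and frequency-response extraction.

A wideband (FM / chirp) echosounder emits a pulse whose instantaneous
frequency sweeps linearly across the band (here 90–170 kHz around a nominal
120 kHz).  On reception, the echo is pulse-compressed by cross-correlating
with a replica of the emitted pulse, which concentrates the echo energy into
a peak of width ~1/bandwidth and allows single targets to be isolated.  The
spectrum of the windowed echo, divided by the spectrum of the replica, is the
target's frequency response; after interpolation onto a fixed grid and
peak-normalization it becomes the frequency response curve (FRC) used by all
downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import hilbert, windows

__all__ = [
    "ChirpConfig",
    "EchoTrace",
    "FRC",
    "FRC_LENGTH",
    "default_frc_grid",
    "make_chirp",
    "apply_fast_ramp",
    "pulse_compress",
    "compressed_peak_delay",
    "extract_frc",
]

#: Number of amplitude samples in a frequency response curve.
FRC_LENGTH = 656

#: Relative spectral floor applied to the replica spectrum before division.
SPECTRAL_FLOOR = 1e-6

#: Guard interval (s) added at each end of the default extraction window so
#: the ringing of a frequency-selective target is captured, not truncated.
WINDOW_GUARD_S = 0.15e-3


class AliasingError(ValueError):
    """Sample rate too low for the configured band."""


@dataclass(frozen=True)
class ChirpConfig:
    """Transmit configuration of the wideband echosounder.

    Defaults follow a 120 kHz wideband transceiver operated in FM mode:
    an 80 kHz sweep from 90 to 170 kHz, 0.512 ms pulse duration, and fast
    ramping that tapers the first and last two wavelengths (at the nominal
    frequency) of the emitted signal.  The sample rate is an implementation
    parameter chosen generously above Nyquist so taper and interpolation
    errors are negligible.
    """

    f_start: float = 90e3
    f_end: float = 170e3
    nominal_f: float = 120e3
    pulse_duration: float = 0.512e-3
    sample_rate: float = 1.5e6
    ramp_wavelengths: int = 2

    def __post_init__(self) -> None:
        if not self.f_start < self.f_end:
            if self.f_start == self.f_end and self.f_start > 0:
                pass  # degenerate pure tone is allowed
            else:
                raise ValueError("f_start must not exceed f_end")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.sample_rate < 2 * self.f_end:
            raise AliasingError(
                f"sample_rate {self.sample_rate} Hz is below Nyquist for "
                f"f_end {self.f_end} Hz"
            )
        if self.ramp_wavelengths < 0:
            raise ValueError("ramp_wavelengths must be nonnegative")

    @property
    def bandwidth(self) -> float:
        return self.f_end - self.f_start

    @property
    def n_samples(self) -> int:
        return int(round(self.pulse_duration * self.sample_rate))


@dataclass
class EchoTrace:
    """A received per-ping time series (pre-compression)."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def default_frc_grid() -> np.ndarray:
    """The fixed 656-point frequency grid spanning 90–170 kHz inclusive (Hz)."""
    return np.linspace(90e3, 170e3, FRC_LENGTH)


@dataclass
class FRC:
    """One normalized frequency response curve.

    ``amplitudes`` are linear (not dB) relative amplitudes on ``freq_grid``,
    peak-normalized so ``max(amplitudes) == 1`` — normalization removes echo
    intensity so only spectral shape remains.
    """

    amplitudes: np.ndarray
    freq_grid: np.ndarray = field(default_factory=default_frc_grid)
    fish_id: str | None = None
    species: str | None = None
    day: int | None = None
    response_idx: int | None = None

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.freq_grid = np.asarray(self.freq_grid, dtype=float)
        if self.amplitudes.shape != (FRC_LENGTH,):
            raise ValueError(f"FRC must have exactly {FRC_LENGTH} samples")
        if self.freq_grid.shape != (FRC_LENGTH,):
            raise ValueError("freq_grid length must match amplitudes")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("FRC amplitudes must be finite")
        if np.any(self.amplitudes <= 0):
            raise ValueError("FRC amplitudes must be strictly positive")
        if not np.isclose(self.amplitudes.max(), 1.0, rtol=0, atol=1e-9):
            raise ValueError("FRC must be peak-normalized (max == 1)")


def make_chirp(config: ChirpConfig) -> np.ndarray:
    """Synthesize the linear FM sweep (unit amplitude, no ramp).

    The instantaneous frequency rises linearly from ``f_start`` at t=0 to
    ``f_end`` at t=pulse_duration; the phase is the integral of the
    instantaneous frequency.
    """
    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    sweep_rate = (config.f_end - config.f_start) / config.pulse_duration
    phase = 2.0 * np.pi * (config.f_start * t + 0.5 * sweep_rate * t**2)
    return np.sin(phase)


def _taper_length(config: ChirpConfig) -> int:
    return int(round(config.ramp_wavelengths / config.nominal_f * config.sample_rate))


def apply_fast_ramp(signal: np.ndarray, config: ChirpConfig) -> np.ndarray:
    """Apply the fast-ramp envelope: cosine tapers over the first and last
    ``ramp_wavelengths`` cycles of the nominal frequency; interior unchanged.
    """
    signal = np.asarray(signal, dtype=float)
    n_taper = _taper_length(config)
    if signal.size <= 2 * n_taper:
        raise ValueError(
            f"signal of {signal.size} samples is too short for two "
            f"{n_taper}-sample tapers"
        )
    out = signal.copy()
    if n_taper == 0:
        return out
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_taper) / n_taper))
    out[:n_taper] *= ramp
    out[-n_taper:] *= ramp[::-1]
    return out


def pulse_compress(echo: EchoTrace, replica: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Matched-filter the echo against the emitted-pulse replica.

    Returns ``(compressed, lags)`` where ``compressed`` is the
    cross-correlation of the echo with the replica normalized by the replica
    energy, and ``lags`` are the corresponding delays in seconds relative to
    ``echo.t0``.  The envelope peak of ``compressed`` estimates the two-way
    travel time of the target; weaker side lobes flank the main peak as an
    intrinsic artifact of matched filtering.
    """
    replica = np.asarray(replica, dtype=float)
    energy = float(np.dot(replica, replica))
    if energy == 0.0:
        raise ValueError("replica has zero energy")
    compressed = np.correlate(echo.samples, replica, mode="full") / energy
    lags = np.arange(-(replica.size - 1), echo.samples.size) / echo.sample_rate
    return compressed, lags


def compressed_peak_delay(echo: EchoTrace, replica: np.ndarray) -> float:
    """Delay (s, relative to ``echo.t0``) of the strongest compressed peak."""
    compressed, lags = pulse_compress(echo, replica)
    envelope = np.abs(hilbert(compressed))
    return float(lags[int(np.argmax(envelope))])


def extract_frc(
    echo: EchoTrace,
    replica: np.ndarray,
    window: tuple[float, float] | None = None,
    grid: np.ndarray | None = None,
    *,
    taper_fraction: float = 0.35,
    fish_id: str | None = None,
    species: str | None = None,
    day: int | None = None,
    response_idx: int | None = None,
) -> FRC:
    """Extract the normalized frequency response curve from a single-target echo.

    The echo is gated with ``window = (start_s, length_s)`` (default: one
    pulse duration starting at the compressed-peak delay, extended by a
    guard interval of 0.15 ms at each end so the ringing tails of a
    frequency-selective target are not truncated), Fourier transformed with
    zero padding, divided by the replica spectrum (floored at ``1e-6`` of its
    in-band maximum), linearly interpolated onto the fixed 656-point grid,
    and peak-normalized.  Scale invariance — ``extract_frc(k * echo)`` equals
    ``extract_frc(echo)`` for any k > 0 — follows from the normalization.

    A Tukey taper covering ``taper_fraction`` of the gated segment (both ends
    combined) suppresses rectangular-window spectral leakage, which would
    otherwise contaminate the response near its peak where the normalized
    amplitude is most sensitive; with the default window the tapered region
    coincides with the guard intervals, leaving the pulse core untouched.
    """
    replica = np.asarray(replica, dtype=float)
    fs = echo.sample_rate
    if grid is None:
        grid = default_frc_grid()
    if window is None:
        delay = compressed_peak_delay(echo, replica)
        guard = WINDOW_GUARD_S
        start = max(delay - guard, echo.t0)
        stop = min(delay + replica.size / fs + guard, echo.t0 + echo.duration)
        window = (start, stop - start)
    start_s, length_s = window
    if length_s * fs < replica.size - 0.5:
        raise ValueError("window length must cover at least one pulse duration")
    i0 = int(round((start_s - echo.t0) * fs))
    i1 = i0 + int(round(length_s * fs))
    if i0 < 0 or i1 > echo.samples.size:
        raise ValueError(
            f"window [{start_s}, {start_s + length_s}] s falls outside the trace"
        )
    segment = echo.samples[i0:i1]
    if not 0.0 <= taper_fraction < 1.0:
        raise ValueError("taper_fraction must lie in [0, 1)")
    if taper_fraction > 0:
        segment = segment * windows.tukey(segment.size, alpha=taper_fraction)

    nfft = 1 << int(np.ceil(np.log2(4 * max(segment.size, replica.size))))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    echo_spec = np.abs(np.fft.rfft(segment, nfft))
    replica_spec = np.abs(np.fft.rfft(replica, nfft))

    in_band = (freqs >= grid[0]) & (freqs <= grid[-1])
    band_max = replica_spec[in_band].max()
    if band_max <= 0:
        raise ValueError("replica spectrum vanishes inside the analysis band")
    floor = SPECTRAL_FLOOR * band_max
    if np.all(replica_spec[in_band] < floor):
        raise ValueError("replica spectrum below numerical floor inside band")
    response = echo_spec / np.maximum(replica_spec, floor)

    amp = np.interp(grid, freqs, response)
    amp = np.maximum(amp, SPECTRAL_FLOOR * max(amp.max(), np.finfo(float).tiny))
    amp = amp / amp.max()
    return FRC(
        amplitudes=amp,
        freq_grid=grid,
        fish_id=fish_id,
        species=species,
        day=day,
        response_idx=response_idx,
    )
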