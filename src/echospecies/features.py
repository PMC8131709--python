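"""Numerical feature descriptor (NFD): a compact summary of an FRC.

The NFD condenses a 656-sample frequency response curve into a small named
feature vector usable as an alternative classifier input.  The default
descriptor has 14 features computed from the dB curve ``20*log10(amplitude)``
(all invariant to echo intensity because the FRC is peak-normalized):

* 8 mean dB levels over equal 10-kHz sub-bands of 90-170 kHz,
* spectral centroid (kHz) of the linear amplitude,
* slope of a least-squares line of dB vs frequency (dB/kHz),
* frequencies (kHz) of the global maximum and global minimum,
* number of local minima at least 3 dB deep relative to their surroundings,
* lag-1 autocorrelation of the dB curve (0 for a constant curve).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import amplitude_columns
from .pulse import FRC, default_frc_grid

__all__ = ["NFDConfig", "compute_nfd", "compute_nfd_table", "NFD_FEATURE_NAMES"]


@dataclass(frozen=True)
class NFDConfig:
    n_bands: int = 8
    min_depth_db: float = 3.0


NFD_FEATURE_NAMES = tuple(
    [f"band_mean_db_{i + 1}" for i in range(8)]
    + [
        "centroid_khz",
        "slope_db_per_khz",
        "argmax_khz",
        "argmin_khz",
        "n_local_minima",
        "lag1_autocorr",
    ]
)


def _feature_names(config: NFDConfig) -> list[str]:
    return [f"band_mean_db_{i + 1}" for i in range(config.n_bands)] + list(
        NFD_FEATURE_NAMES[8:]
    )


def compute_nfd(
    amplitudes: np.ndarray | FRC,
    freq_grid: np.ndarray | None = None,
    config: NFDConfig = NFDConfig(),
) -> pd.Series:
    """Compute the numerical feature descriptor of one FRC."""
    if isinstance(amplitudes, FRC):
        freq_grid = amplitudes.freq_grid
        amplitudes = amplitudes.amplitudes
    amplitudes = np.asarray(amplitudes, dtype=float)
    if freq_grid is None:
        freq_grid = default_frc_grid()
    if not np.all(np.isfinite(amplitudes)) or np.any(amplitudes <= 0):
        raise ValueError("FRC amplitudes must be finite and positive")
    fk = np.asarray(freq_grid, dtype=float) / 1e3
    db = 20.0 * np.log10(amplitudes)

    edges = np.linspace(fk[0], fk[-1], config.n_bands + 1)
    band_means = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (fk >= lo) & (fk <= hi) if hi == edges[-1] else (fk >= lo) & (fk < hi)
        band_means.append(db[mask].mean())

    centroid = float(np.sum(fk * amplitudes) / np.sum(amplitudes))
    slope = float(np.polyfit(fk, db, 1)[0])
    argmax_khz = float(fk[int(np.argmax(amplitudes))])
    argmin_khz = float(fk[int(np.argmin(amplitudes))])
    minima, _ = find_peaks(-db, prominence=config.min_depth_db)
    centered = db - db.mean()
    denom = float(np.sum(centered**2))
    lag1 = float(np.sum(centered[1:] * centered[:-1]) / denom) if denom > 1e-12 else 0.0

    values = band_means + [centroid, slope, argmax_khz, argmin_khz, float(minima.size), lag1]
    return pd.Series(values, index=_feature_names(config), dtype=float)


def compute_nfd_table(frc_table: pd.DataFrame, config: NFDConfig = NFDConfig()) -> pd.DataFrame:
    """One NFD row per response, keeping the identifying columns."""
    amp_cols = amplitude_columns(frc_table)
    grid = default_frc_grid() if len(amp_cols) == 656 else np.arange(len(amp_cols), dtype=float)
    feats = np.vstack(
        [
            compute_nfd(row, grid, config).to_numpy()
            for row in frc_table[amp_cols].to_numpy()
        ]
    )
    meta_cols = [c for c in ("fish_id", "species", "day", "response_idx") if c in frc_table]
    out = frc_table[meta_cols].reset_index(drop=True)
    return pd.concat(
        [out, pd.DataFrame(feats, columns=_feature_names(config))], axis=1
    )
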