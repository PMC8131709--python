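"""Intra- and inter-individual variation of logit-transformed frequency
response curves.

Normalized FRC amplitudes live in (0, 1], so deviations on the raw scale are
bounded and asymmetric.  The curves are therefore logit transformed first;
deviations and their mean absolute values (MAD) are computed on that
unbounded scale, per species, per frequency, and summarized across all
frequencies into a grand MAD:

* intra-individual deviation: response value minus that fish's mean value,
* inter-individual deviation: fish mean minus the species mean.

Amplitudes are clipped into ``[eps, 1 - eps]`` before the transform.  The
default ``eps = 1e-3`` bounds transformed values at about +/-6.9: grid bins
within one part in a thousand of the normalized maximum carry no reliable
shape information (the logit would amplify any relative amplitude error
there by ~1/eps), so a larger floor would discard signal while a smaller
one lets extraction noise near the spectral peak dominate the deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import amplitude_columns

__all__ = ["MADSummary", "logit_frc", "mad_decomposition"]

DEFAULT_EPS = 1e-3


def logit_frc(amplitudes: np.ndarray, eps: float = DEFAULT_EPS) -> np.ndarray:
    """Logit transform amplitudes in (0, 1], clipping into [eps, 1 - eps].

    Peak normalization makes the maximum exactly 1, which must be clipped
    before the transform; ``eps`` bounds the transformed values at
    ``log((1 - eps) / eps)``.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError("eps must lie strictly between 0 and 0.5")
    x = np.clip(np.asarray(amplitudes, dtype=float), eps, 1.0 - eps)
    return np.log(x / (1.0 - x))


@dataclass
class MADSummary:
    """Per-frequency and grand mean absolute deviations per species."""

    freq_grid: np.ndarray
    per_frequency_intra: dict[str, np.ndarray]
    per_frequency_inter: dict[str, np.ndarray]
    grand_intra: dict[str, float]
    grand_inter: dict[str, float]

    @property
    def species(self) -> list[str]:
        return sorted(self.grand_intra)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: species x frequency rows plus grand rows."""
        rows = []
        for sp in self.species:
            for f, intra, inter in zip(
                self.freq_grid, self.per_frequency_intra[sp], self.per_frequency_inter[sp]
            ):
                rows.append((sp, f, intra, inter))
            rows.append((sp, np.nan, self.grand_intra[sp], self.grand_inter[sp]))
        return pd.DataFrame(rows, columns=["species", "frequency_hz", "intra_mad", "inter_mad"])


def mad_decomposition(
    table: pd.DataFrame, eps: float = DEFAULT_EPS, freq_grid: np.ndarray | None = None
) -> MADSummary:
    """Decompose logit-FRC variation into intra- and inter-individual MADs.

    Requires at least two responses per fish (to separate a response from
    its fish mean) and at least two fish per species (to define the species
    mean of fish means).  The grand MAD is the average of the per-frequency
    MADs; deviation counts are equal across frequencies, so this matches the
    mean over all deviations.
    """
    from .pulse import default_frc_grid

    amp_cols = amplitude_columns(table)
    if freq_grid is None:
        freq_grid = default_frc_grid() if len(amp_cols) == 656 else np.arange(len(amp_cols), dtype=float)

    per_intra: dict[str, np.ndarray] = {}
    per_inter: dict[str, np.ndarray] = {}
    grand_intra: dict[str, float] = {}
    grand_inter: dict[str, float] = {}
    for sp, sub in table.groupby("species", sort=True):
        fish_sizes = sub.groupby("fish_id").size()
        if (fish_sizes < 2).any():
            bad = fish_sizes[fish_sizes < 2].index[0]
            raise ValueError(f"fish {bad!r} has fewer than 2 responses")
        if len(fish_sizes) < 2:
            raise ValueError(
                f"species {sp!r} has a single fish; inter-individual MAD undefined"
            )
        values = logit_frc(sub[amp_cols].to_numpy(), eps)
        fish_means = (
            pd.DataFrame(values, index=sub["fish_id"].to_numpy())
            .groupby(level=0)
            .mean()
        )
        intra_dev = values - fish_means.loc[sub["fish_id"]].to_numpy()
        inter_dev = fish_means.to_numpy() - fish_means.to_numpy().mean(axis=0)
        per_intra[sp] = np.abs(intra_dev).mean(axis=0)
        per_inter[sp] = np.abs(inter_dev).mean(axis=0)
        grand_intra[sp] = float(per_intra[sp].mean())
        grand_inter[sp] = float(per_inter[sp].mean())
    return MADSummary(
        freq_grid=np.asarray(freq_grid, dtype=float),
        per_frequency_intra=per_intra,
        per_frequency_inter=per_inter,
        grand_intra=grand_intra,
        grand_inter=grand_inter,
    )
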