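"""Fish orientation (aspect angle) from tracked positions.

The aspect angle is measured relative to the water surface: 0 deg is
horizontal swimming, 90 deg vertical.  It is estimated from consecutive
tracked positions as ``atan`` of the mean absolute vertical displacement
rate over the mean horizontal displacement rate; ascending and descending
movement are equivalent.  Angles are grouped into the three classes
low [0, 20), medium [20, 40), and high [40, 90], and species classification
accuracy can be re-estimated within each class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import FishTrack

__all__ = [
    "OrientationEstimate",
    "OrientationClassAccuracy",
    "classify_orientation",
    "estimate_orientation",
    "accuracy_by_orientation",
    "ORIENTATION_CLASSES",
]

ORIENTATION_CLASSES = ("low", "medium", "high")

DEFAULT_MIN_DISPLACEMENT = 0.10  # m of total path length for a reliable estimate


@dataclass
class OrientationEstimate:
    fish_id: str
    angle_deg: float
    angle_class: str
    n_positions_used: int
    reliable: bool


@dataclass
class OrientationClassAccuracy:
    """Grouped-CV accuracy within one orientation class, or an insufficiency flag."""

    angle_class: str
    n_fish: dict[str, int]
    sufficient: bool
    accuracy_mean: float | None = None
    accuracy_sd: float | None = None
    accuracies: np.ndarray | None = None


def classify_orientation(angle_deg: float) -> str:
    """Map an aspect angle to its class: low [0,20), medium [20,40), high [40,90]."""
    if not 0.0 <= angle_deg <= 90.0:
        raise ValueError("orientation angle must lie in [0, 90] degrees")
    if angle_deg < 20.0:
        return "low"
    if angle_deg < 40.0:
        return "medium"
    return "high"


def estimate_orientation(
    track: FishTrack, min_displacement: float = DEFAULT_MIN_DISPLACEMENT
) -> OrientationEstimate:
    """Estimate the aspect angle of one fish from its track.

    The estimate is invariant to translation of the track and to rotation of
    the horizontal coordinates.  Targets whose total path length is below
    ``min_displacement`` moved too little for a reliable estimate and are
    flagged ``reliable=False``.
    """
    pos = track.positions
    dt = np.diff(pos[:, 0])
    dx, dy, dz = (np.diff(pos[:, i]) for i in (1, 2, 3))
    horiz = np.hypot(dx, dy)
    v_rate = float(np.mean(np.abs(dz) / dt))
    h_rate = float(np.mean(horiz / dt))
    if v_rate == 0.0 and h_rate == 0.0:
        angle = 0.0
    else:
        angle = float(np.degrees(np.arctan2(v_rate, h_rate)))
    path_length = float(np.sum(np.hypot(horiz, dz)))
    return OrientationEstimate(
        fish_id=track.fish_id,
        angle_deg=angle,
        angle_class=classify_orientation(angle),
        n_positions_used=pos.shape[0],
        reliable=path_length >= min_displacement,
    )


def estimates_to_frame(estimates: list[OrientationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (e.fish_id, e.angle_deg, e.angle_class, e.n_positions_used, e.reliable)
            for e in estimates
        ],
        columns=["fish_id", "angle_deg", "angle_class", "n_positions_used", "reliable"],
    )


def accuracy_by_orientation(
    table: pd.DataFrame,
    estimates: list[OrientationEstimate] | pd.DataFrame,
    forest_config=None,
    cv_config=None,
    min_fish_per_species: int = 4,
) -> dict[str, OrientationClassAccuracy]:
    """Grouped-CV classification accuracy within each orientation class.

    Classes where either species has fewer than ``min_fish_per_species``
    targets are flagged insufficient rather than scored (too few targets
    give no meaningful accuracy estimate).
    """
    from .classify import CVConfig, ForestConfig, grouped_cv

    forest_config = forest_config or ForestConfig()
    cv_config = cv_config or CVConfig()
    if not isinstance(estimates, pd.DataFrame):
        estimates = estimates_to_frame(estimates)
    class_of = dict(zip(estimates["fish_id"], estimates["angle_class"]))

    results: dict[str, OrientationClassAccuracy] = {}
    for cls in ORIENTATION_CLASSES:
        fish = [f for f, c in class_of.items() if c == cls]
        sub = table[table["fish_id"].isin(fish)]
        n_fish = {
            sp: int(sub[sub["species"] == sp]["fish_id"].nunique())
            for sp in ("stickleback", "whitefish")
        }
        if any(n < min_fish_per_species for n in n_fish.values()):
            results[cls] = OrientationClassAccuracy(cls, n_fish, sufficient=False)
            continue
        cv = grouped_cv(sub, forest_config, cv_config)
        results[cls] = OrientationClassAccuracy(
            cls,
            n_fish,
            sufficient=True,
            accuracy_mean=float(np.mean(cv.accuracies)),
            accuracy_sd=float(np.std(cv.accuracies, ddof=1)),
            accuracies=cv.accuracies,
        )
    return results
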