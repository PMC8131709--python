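"""Readers and writers for the pipeline's table formats.

The primary interchange format is a wide CSV with one row per frequency
response: ``fish_id, species, day, response_idx, a_0001 .. a_0656`` (one
column per frequency-grid point).  Tracks, orientation estimates, MAD
summaries, and importance curves use small long-format CSVs.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "amplitude_columns",
    "predictor_columns",
    "frc_table_columns",
    "read_frc_table",
    "write_frc_table",
    "read_tracks",
    "write_tracks",
]

log = logging.getLogger("echospecies")

META_COLUMNS = ("fish_id", "species", "day", "response_idx")
_AMP_RE = re.compile(r"^a_(\d{4})$")
VALID_SPECIES = {"stickleback", "whitefish", ""}


def frc_table_columns(n_amplitudes: int = 656) -> list[str]:
    return list(META_COLUMNS) + [f"a_{i + 1:04d}" for i in range(n_amplitudes)]


def amplitude_columns(table: pd.DataFrame) -> list[str]:
    """The ``a_XXXX`` amplitude columns of a wide FRC table, in order."""
    cols = sorted((c for c in table.columns if _AMP_RE.match(c)))
    if not cols:
        raise ValueError("table has no amplitude columns (a_0001 ...)")
    return cols


def predictor_columns(table: pd.DataFrame) -> list[str]:
    """Predictor columns: amplitude columns if present, else every
    non-identifier column (NFD feature tables)."""
    amp = sorted(c for c in table.columns if _AMP_RE.match(c))
    if amp:
        return amp
    cols = [c for c in table.columns if c not in META_COLUMNS]
    if not cols:
        raise ValueError("table has no predictor columns")
    return cols


class SchemaError(ValueError):
    """The file does not match the expected table schema."""


def _validate_frc_schema(columns: list[str], n_amplitudes: int = 656) -> None:
    expected = frc_table_columns(n_amplitudes)
    missing = [c for c in expected if c not in columns]
    extra = [c for c in columns if c not in expected]
    if missing or extra:
        detail = []
        if missing:
            detail.append(f"missing column(s) {missing[:3]}")
        if extra:
            detail.append(f"unexpected column(s) {extra[:3]}")
        raise SchemaError(
            f"FRC table must have columns fish_id, species, day, response_idx, "
            f"a_0001..a_{n_amplitudes:04d}; " + "; ".join(detail)
        )


def read_frc_table(path: str | Path, n_amplitudes: int = 656) -> pd.DataFrame:
    """Read and validate a wide-format FRC table.

    Species labels are normalized to lowercase (logged when changed); a
    wrong amplitude-column count raises a schema error naming the offending
    columns, and non-numeric amplitudes raise a parse error with the row
    number.
    """
    table = pd.read_csv(path, dtype={"fish_id": str, "species": str})
    _validate_frc_schema(list(table.columns), n_amplitudes)
    amp_cols = amplitude_columns(table)
    for col in amp_cols:
        values = pd.to_numeric(table[col], errors="coerce")
        bad = values.index[values.isna() & table[col].notna()]
        if len(bad) or table[col].isna().any():
            row = int(bad[0]) if len(bad) else int(table[col].index[table[col].isna()][0])
            raise ValueError(f"non-numeric amplitude in column {col}, data row {row + 1}")
        table[col] = values
    table["species"] = table["species"].fillna("")
    lowered = table["species"].str.lower()
    changed = (lowered != table["species"]).sum()
    if changed:
        log.info("normalized %d species labels to lowercase", changed)
    table["species"] = lowered
    unknown = set(table["species"]) - VALID_SPECIES
    if unknown:
        raise ValueError(f"unknown species label(s): {sorted(unknown)}")
    table["day"] = table["day"].astype(int)
    table["response_idx"] = table["response_idx"].astype(int)
    return table


def write_frc_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a wide-format FRC table (lossless float round trip)."""
    _validate_frc_schema(list(table.columns), len(amplitude_columns(table)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_tracks(tracks, path: str | Path) -> None:
    """Write fish tracks as a long CSV (one row per position)."""
    rows = []
    for track in tracks:
        for t, x, y, z in track.positions:
            rows.append((track.fish_id, t, x, y, z, track.true_orientation_deg))
    frame = pd.DataFrame(
        rows, columns=["fish_id", "time_s", "x_m", "y_m", "z_m", "true_orientation_deg"]
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)


def read_tracks(path: str | Path):
    """Read a tracks CSV back into a list of FishTrack objects."""
    from .simulate import FishTrack

    frame = pd.read_csv(path, dtype={"fish_id": str})
    required = {"fish_id", "time_s", "x_m", "y_m", "z_m"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"tracks CSV is missing column(s) {sorted(missing)}")
    tracks = []
    for fish_id, sub in frame.groupby("fish_id", sort=True):
        sub = sub.sort_values("time_s")
        angle = None
        if "true_orientation_deg" in sub and sub["true_orientation_deg"].notna().any():
            angle = float(sub["true_orientation_deg"].iloc[0])
        tracks.append(
            FishTrack(
                fish_id=str(fish_id),
                positions=sub[["time_s", "x_m", "y_m", "z_m"]].to_numpy(float),
                true_orientation_deg=angle,
            )
        )
    return tracks
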