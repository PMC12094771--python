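"""Delimited-text serialization of trajectories and sweep grids.

All files are UTF-8, comma-delimited, LF-terminated, with a header row and
full repr-precision floats (Python's shortest round-trip representation),
so writing then reading reproduces every value bit-exactly and downstream
comparisons need no tolerance.
"""

from __future__ import annotations

import pandas as pd

from .core import STATE_FIELDS
from .simulate import Trajectory
from .sweeps import SweepGrid

__all__ = ["write_trajectory", "read_trajectory", "write_grid", "read_grid"]

TRAJECTORY_COLUMNS = ("t",) + STATE_FIELDS


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write one row per time point with columns t, C1, C2, C3, N1, N2, N3, T."""
    frame = trajectory.to_dataframe()
    frame.to_csv(path, index=False, lineterminator="\n")


def read_trajectory(path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = list(TRAJECTORY_COLUMNS)
    if list(frame.columns) != expected:
        raise ValueError(f"not a trajectory file: columns {list(frame.columns)} != {expected}")
    return frame


def _grids_frame(grid) -> pd.DataFrame:
    """Accept one SweepGrid or a mapping of them (multi-variant/-scenario sweeps)."""
    if isinstance(grid, SweepGrid):
        frame = grid.to_dataframe()
    else:
        frame = pd.concat([g.to_dataframe() for g in grid.values()], ignore_index=True)
    # lexicographic column order makes the layout deterministic regardless
    # of which sweep produced the grid
    return frame.reindex(columns=sorted(frame.columns))


def write_grid(grid, path) -> None:
    """Write a sweep grid (or dict of grids) in long format, one row per cell.

    Failed cells keep their row: ``converged`` is False and the frequency
    and ``t_final`` fields are empty. An empty grid yields a header-only
    file.
    """
    _grids_frame(grid).to_csv(path, index=False, lineterminator="\n")


def read_grid(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
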