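"""Cell-migration metrics: total distance, net/total speed, persistence.

Persistence is the straight-line distance between a track's origin and end
point divided by the total distance traveled; speeds are reported per hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["Trajectory", "MotilitySummary", "summarize_track", "batch_summarize"]

METRICS = ("total_distance", "net_displacement", "net_speed", "total_speed",
           "persistence")


@dataclass
class Trajectory:
    """A tracked cell path: times in minutes, positions in microns (x, y).

    Physical coordinates: x east, y up (counter-clockwise angles, east = 0).
    """

    cell_id: str
    times: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n, 2) array")
        if self.times.shape[0] != self.positions.shape[0]:
            raise ValueError("times and positions must have equal length")
        if self.times.size < 2:
            raise ValueError("a trajectory needs at least 2 points")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_points(self) -> int:
        return self.times.size

    def step_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions, axis=0), axis=1)


@dataclass
class MotilitySummary:
    cell_id: str
    total_distance: float      # µm
    net_displacement: float    # µm
    duration: float            # hours
    net_speed: float           # µm/h
    total_speed: float         # µm/h
    persistence: float         # dimensionless, in [0, 1]


def summarize_track(track: Trajectory) -> MotilitySummary:
    """Compute the migration metrics of one track.

    total distance = sum of consecutive step lengths; net displacement =
    straight-line origin-to-end distance; speeds divide by the duration in
    hours; persistence = net / total (1.0 by convention for a stationary
    cell, logged as a warning).
    """
    steps = track.step_lengths()
    total = float(steps.sum())
    net = float(np.linalg.norm(track.positions[-1] - track.positions[0]))
    duration_h = float(track.times[-1] - track.times[0]) / 60.0
    if duration_h <= 0:
        raise ValueError("track duration must be positive")
    if total == 0.0:
        log.warning("track %s is stationary; persistence set to 1.0", track.cell_id)
        persistence = 1.0
    else:
        persistence = net / total
    return MotilitySummary(
        cell_id=track.cell_id,
        total_distance=total,
        net_displacement=net,
        duration=duration_h,
        net_speed=net / duration_h,
        total_speed=total / duration_h,
        persistence=persistence,
    )


def summaries_to_frame(summaries: list[MotilitySummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def batch_summarize(
    tracks: list[Trajectory], group_labels: list[str]
) -> pd.DataFrame:
    """Per-group mean, s.e.m. and n of every migration metric.

    Returns a DataFrame indexed by group with columns
    ``<metric>_mean``, ``<metric>_sem`` and ``n``.
    """
    if len(tracks) != len(group_labels):
        raise ValueError("tracks and group_labels must have equal length")
    if not tracks:
        raise ValueError("no tracks given")
    rows = summaries_to_frame([summarize_track(t) for t in tracks])
    rows["group"] = list(group_labels)
    out = {}
    for group, sub in rows.groupby("group", sort=True):
        if sub.empty:
            raise ValueError(f"group {group!r} has no tracks")
        entry: dict[str, float] = {}
        for metric in METRICS:
            entry[f"{metric}_mean"] = float(sub[metric].mean())
            sem = float(sub[metric].sem()) if len(sub) > 1 else 0.0
            entry[f"{metric}_sem"] = sem
        entry["n"] = len(sub)
        out[group] = entry
    table = pd.DataFrame(out).T
    table.index.name = "group"
    table["n"] = table["n"].astype(int)
    return table
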