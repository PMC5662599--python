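"""Front-rear polarity statistics from ratio images.

The cell is split into a back and a front half by the line through the
centroid perpendicular to the front direction; the FRET index of a region
is the mean of the defined normalized ratio pixels inside it.  The module
also provides fixed region-pair (A/B) time series with repolarization
detection, line-scan intensity profiles, profile correlation, and heat-map
matrices across cells.

Conventions: physical coordinates in microns with y pointing up (row 0 is
the top of the image, so y = (H-1-row) * pixel_size); angles in degrees,
east = 0, counter-clockwise positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.stats import pearsonr

from .motility import Trajectory
from .ratio import CellMask, RatioImage

log = logging.getLogger(__name__)

__all__ = [
    "PolarityAxis",
    "PolarityRecord",
    "LineScanProfile",
    "HeatmapMatrix",
    "derive_axis_from_track",
    "back_front_indices",
    "region_pair_series",
    "detect_crossing",
    "line_scan",
    "profile_correlation",
    "build_heatmap",
]


def raster_to_um(rows: np.ndarray, cols: np.ndarray, shape: tuple[int, int],
                 pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Pixel indices -> physical (x, y) in microns, y up."""
    x = np.asarray(cols, dtype=float) * pixel_size
    y = (shape[0] - 1 - np.asarray(rows, dtype=float)) * pixel_size
    return x, y


def um_to_raster(x: np.ndarray, y: np.ndarray, shape: tuple[int, int],
                 pixel_size: float) -> tuple[np.ndarray, np.ndarray]:
    """Physical microns -> fractional (row, col) raster coordinates."""
    col = np.asarray(x, dtype=float) / pixel_size
    row = (shape[0] - 1) - np.asarray(y, dtype=float) / pixel_size
    return row, col


@dataclass
class PolarityAxis:
    """Front direction of a cell at one frame."""

    centroid: np.ndarray          # (x, y) in µm
    front_direction: float        # degrees in [0, 360)
    source: str = "from_migration"  # or "annotated"

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.front_direction = float(self.front_direction) % 360.0

    def flipped(self) -> "PolarityAxis":
        return PolarityAxis(self.centroid.copy(),
                            (self.front_direction + 180.0) % 360.0,
                            self.source)


@dataclass
class PolarityRecord:
    """Back/front/total FRET indices of one cell at one frame.

    ``reason`` is None for a valid record; otherwise it names why the
    record is undefined (e.g. too few defined pixels in a half).
    """

    cell_id: str
    frame: int
    time: float                 # minutes
    back_index: float = np.nan
    front_index: float = np.nan
    back_front_ratio: float = np.nan
    total_index: float = np.nan
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


@dataclass
class LineScanProfile:
    """Fluorescence intensity sampled along a polyline.

    ``normalized_position`` runs from 0 at the first vertex (leading edge)
    to 1 at the last vertex (perinuclear end).
    """

    arclength: np.ndarray        # µm, strictly increasing
    intensity: np.ndarray
    normalized_position: np.ndarray
    averaging_width: int = 3

    def __post_init__(self) -> None:
        self.arclength = np.asarray(self.arclength, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.normalized_position = np.asarray(self.normalized_position, dtype=float)
        if self.arclength.size < 2:
            raise ValueError("a profile needs at least 2 samples")
        if np.any(np.diff(self.arclength) <= 0):
            raise ValueError("arclength must be strictly increasing")


@dataclass
class HeatmapMatrix:
    """Cells x time matrix of a polarity quantity."""

    values: np.ndarray
    rows: list[str]
    columns: np.ndarray          # time points, minutes
    quantity: str
    row_order: str = "as_given"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.rows, columns=self.columns)


def derive_axis_from_track(track: Trajectory, frame: int,
                           lookahead: int = 1) -> PolarityAxis:
    """Front direction from the subsequent net displacement of a track."""
    if lookahead < 1:
        raise ValueError("lookahead must be >= 1")
    if frame < 0 or frame + lookahead >= track.n_points:
        raise ValueError(
            f"track has no frame {frame + lookahead}; cannot look ahead")
    delta = track.positions[frame + lookahead] - track.positions[frame]
    norm = float(np.linalg.norm(delta))
    if norm == 0.0:
        raise ValueError(
            "zero displacement over the lookahead window; "
            "use an annotated axis for this frame")
    angle = float(np.degrees(np.arctan2(delta[1], delta[0]))) % 360.0
    return PolarityAxis(centroid=track.positions[frame].copy(),
                        front_direction=angle, source="from_migration")


def back_front_indices(
    ratio: RatioImage,
    mask: CellMask | np.ndarray,
    axis: PolarityAxis,
    pixel_size: float,
    cell_id: str = "cell",
    frame: int = 0,
    time: float = 0.0,
    min_pixels: int = 10,
) -> PolarityRecord:
    """Back and front FRET indices and their ratio for one frame.

    The mask is split by the line through the axis centroid perpendicular
    to the front direction; pixels whose projection onto the front unit
    vector is >= 0 belong to the front half.  Halves with fewer than
    ``min_pixels`` defined pixels yield an undefined record with a reason
    code instead of an exception.
    """
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask).astype(bool)
    defined = ratio.defined_mask & m
    rows, cols = np.nonzero(defined)
    if rows.size == 0:
        return PolarityRecord(cell_id, frame, time, reason="no_defined_pixels")
    x, y = raster_to_um(rows, cols, m.shape, pixel_size)
    theta = np.radians(axis.front_direction)
    proj = (x - axis.centroid[0]) * np.cos(theta) + (y - axis.centroid[1]) * np.sin(theta)
    vals = ratio.values[rows, cols]
    front = proj >= 0
    n_front, n_back = int(front.sum()), int((~front).sum())
    if n_front < min_pixels or n_back < min_pixels:
        return PolarityRecord(cell_id, frame, time,
                              reason=f"half_underpopulated:front={n_front},back={n_back}")
    front_index = float(vals[front].mean())
    back_index = float(vals[~front].mean())
    return PolarityRecord(
        cell_id=cell_id, frame=frame, time=time,
        back_index=back_index, front_index=front_index,
        back_front_ratio=back_index / front_index,
        total_index=float(vals.mean()),
    )


def region_pair_series(
    ratios: Sequence[RatioImage],
    region_a: np.ndarray,
    region_b: np.ndarray,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-frame mean ratio in two fixed regions A and B, plus B/A.

    Regions are fixed in the lab frame across the movie; frames where a
    region misses the defined mask are flagged undefined (NaN) rather than
    raising.  Columns: frame, time, mean_a, mean_b, b_over_a, defined.
    """
    region_a = np.asarray(region_a).astype(bool)
    region_b = np.asarray(region_b).astype(bool)
    if times is None:
        times = np.arange(len(ratios), dtype=float)
    rows = []
    for i, ratio in enumerate(ratios):
        rec: dict = {"frame": i, "time": float(times[i])}
        in_a = ratio.defined_mask & region_a
        in_b = ratio.defined_mask & region_b
        if in_a.any() and in_b.any():
            mean_a = float(ratio.values[in_a].mean())
            mean_b = float(ratio.values[in_b].mean())
            rec.update(mean_a=mean_a, mean_b=mean_b,
                       b_over_a=mean_b / mean_a, defined=True)
        else:
            log.warning("frame %d: region %s does not meet the defined mask",
                        i, "A" if not in_a.any() else "B")
            rec.update(mean_a=np.nan, mean_b=np.nan, b_over_a=np.nan,
                       defined=False)
        rows.append(rec)
    return pd.DataFrame(rows)


def detect_crossing(series: pd.DataFrame | np.ndarray,
                    level: float = 1.0) -> int | None:
    """First frame at which the B/A series crosses ``level``.

    Scans consecutive defined values and returns the frame index of the
    first value on the opposite side of ``level`` from the series start
    (or exactly at it); None when no crossing occurs.
    """
    if isinstance(series, pd.DataFrame):
        frames = series["frame"].to_numpy()
        values = series["b_over_a"].to_numpy()
    else:
        values = np.asarray(series, dtype=float)
        frames = np.arange(values.size)
    ok = np.isfinite(values)
    frames, values = frames[ok], values[ok]
    if values.size < 2:
        return None
    start_side = np.sign(values[0] - level)
    if start_side == 0:
        return int(frames[0])
    for f, v in zip(frames[1:], values[1:]):
        if np.sign(v - level) != start_side:
            return int(f)
    return None


def line_scan(
    image: np.ndarray,
    polyline_um: np.ndarray,
    pixel_size: float,
    averaging_width: int = 3,
    step: float | None = None,
) -> LineScanProfile:
    """Sample mean intensity along a polyline by bilinear interpolation.

    Samples every ``step`` microns of arclength (default: one pixel) and
    averages ``averaging_width`` bilinear samples spaced one pixel apart
    perpendicular to the local direction.
    """
    image = np.asarray(image, dtype=float)
    pts = np.asarray(polyline_um, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("polyline must be an (n>=2, 2) array of µm coordinates")
    if step is None:
        step = pixel_size
    if step <= 0:
        raise ValueError("step must be positive")
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    if np.any(seg_len == 0):
        raise ValueError("polyline has zero-length segments")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = float(cum[-1])
    if total < step:
        raise ValueError("polyline is shorter than one step")
    s = np.arange(0.0, total + step / 2, step)
    s = s[s <= total]
    # segment index for each sample; the end point uses the last segment
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    pos = pts[idx] + seg[idx] * frac[:, None]
    u = seg[idx] / seg_len[idx][:, None]
    normal = np.stack([-u[:, 1], u[:, 0]], axis=1)
    offsets = (np.arange(averaging_width) - (averaging_width - 1) / 2.0) * pixel_size
    samples = np.empty((len(s), averaging_width))
    for j, off in enumerate(offsets):
        p = pos + normal * off
        row, col = um_to_raster(p[:, 0], p[:, 1], image.shape, pixel_size)
        samples[:, j] = ndi.map_coordinates(image, [row, col], order=1,
                                            mode="nearest")
    return LineScanProfile(
        arclength=s,
        intensity=samples.mean(axis=1),
        normalized_position=s / total,
        averaging_width=averaging_width,
    )


def profile_correlation(
    p1: LineScanProfile, p2: LineScanProfile, n_samples: int | None = None
) -> tuple[float, int]:
    """Pearson correlation of two profiles on a common position grid.

    Both profiles are linearly resampled onto a uniform grid over
    normalized position [0, 1]; returns ``(r, n)``.
    """
    if n_samples is None:
        n_samples = min(p1.intensity.size, p2.intensity.size)
    if n_samples < 3:
        raise ValueError("need at least 3 common samples for a correlation")
    grid = np.linspace(0.0, 1.0, n_samples)
    a = np.interp(grid, p1.normalized_position, p1.intensity)
    b = np.interp(grid, p2.normalized_position, p2.intensity)
    r = float(pearsonr(a, b).statistic)
    return r, n_samples


def records_to_frame(records: Sequence[PolarityRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def build_heatmap(
    records_by_cell: dict[str, Sequence[PolarityRecord]],
    quantity: str = "back_front_ratio",
    row_order: str = "by_mean",
) -> HeatmapMatrix:
    """Cells x time matrix of one polarity quantity.

    Cells are aligned on a common time base (union of record times,
    nearest-neighbour fill for missing interior values).  ``by_mean``
    orders rows by descending time-mean.
    """
    if not records_by_cell:
        raise ValueError("no cells given")
    if row_order not in ("by_mean", "as_given"):
        raise ValueError("row_order must be 'by_mean' or 'as_given'")
    frames = {}
    for cid, recs in records_by_cell.items():
        df = records_to_frame(list(recs))
        df = df[df["reason"].isna()]
        frames[cid] = df.set_index("time")[quantity]
    table = pd.DataFrame(frames).T  # rows = cells, columns = times
    table = table[sorted(table.columns)]
    # nearest-neighbour fill along time so interior gaps do not stay NaN
    if table.isna().any().any():
        table = table.interpolate(method="nearest", axis=1,
                                  limit_direction="both")
        table = table.ffill(axis=1).bfill(axis=1)
    if row_order == "by_mean":
        order = table.mean(axis=1).sort_values(ascending=False).index
        table = table.loc[order]
    return HeatmapMatrix(
        values=table.to_numpy(),
        rows=list(table.index),
        columns=np.asarray(table.columns, dtype=float),
        quantity=quantity,
        row_order=row_order,
    )
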