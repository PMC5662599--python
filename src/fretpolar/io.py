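"""Readers and writers for the pipeline's on-disk formats.

Movies are 2-channel multi-page TIFF (channel order donor, FRET; page
order frame-major), masks single-channel TIFF stacks, trajectories CSV
(cell_id, frame, t_min, x_um, y_um), ground truth a JSON sidecar with all
generation parameters echoed, ratio stacks 32-bit float TIFF with an 8-bit
pseudocolor PNG preview.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .motility import MotilitySummary, Trajectory
from .polarity import HeatmapMatrix, LineScanProfile, PolarityRecord
from .protrusions import PolarHistogram, Protrusion
from .ratio import RatioImage, TwoChannelMovie
from .synthetic import GroundTruth

TRAJECTORY_COLUMNS = ["cell_id", "frame", "t_min", "x_um", "y_um"]


# ---------------------------------------------------------------- movies

def write_movie_tiff(path: str | Path, movie: TwoChannelMovie) -> None:
    """Donor/FRET stack as multi-page TIFF, frame-major page order."""
    stack = np.stack([movie.donor_frames, movie.fret_frames], axis=1)
    meta = {
        "pixel_size_um": movie.pixel_size,
        "frame_interval_min": movie.frame_interval,
        "frame_times_min": movie.frame_times.tolist(),
        "channels": ["donor", "fret"],
    }
    pages = stack.reshape(-1, *stack.shape[2:]).astype(np.float32)
    tifffile.imwrite(path, pages, photometric='minisblack',
                     description=json.dumps(meta))


def read_movie_tiff(path: str | Path) -> TwoChannelMovie:
    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc)
    n_frames = pages.shape[0] // 2
    stack = pages.reshape(n_frames, 2, *pages.shape[1:])
    return TwoChannelMovie(
        donor_frames=stack[:, 0], fret_frames=stack[:, 1],
        pixel_size=float(meta["pixel_size_um"]),
        frame_interval=float(meta["frame_interval_min"]),
        frame_times=np.asarray(meta["frame_times_min"], dtype=float),
    )


def write_mask_tiff(path: str | Path, masks: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(masks).astype(np.uint8),
                     photometric='minisblack')


def read_mask_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path).astype(bool)


def write_ratio_tiff(path: str | Path, ratios: list[RatioImage]) -> None:
    stack = np.stack([r.values for r in ratios]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric='minisblack')


# ------------------------------------------------------------ trajectories

def write_trajectories(path: str | Path, tracks: list[Trajectory]) -> None:
    rows = []
    for track in tracks:
        for i in range(track.n_points):
            rows.append({
                "cell_id": track.cell_id, "frame": i,
                "t_min": track.times[i],
                "x_um": track.positions[i, 0], "y_um": track.positions[i, 1],
            })
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_trajectories(path: str | Path) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    tracks = []
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame")
        tracks.append(Trajectory(
            cell_id=str(cid), times=sub["t_min"].to_numpy(),
            positions=sub[["x_um", "y_um"]].to_numpy(),
        ))
    return tracks


# ------------------------------------------------------------ ground truth

def write_ground_truth(json_path: str | Path, truth: GroundTruth,
                       masks_tiff: str | Path | None = None,
                       activation_tiff: str | Path | None = None) -> None:
    """JSON sidecar with parameters and per-frame scalar truth; the dense
    mask and activation stacks go to TIFF when paths are given."""
    payload = {
        "params": _jsonable(truth.params),
        "true_centroid_track_um": truth.true_centroid_track.tolist(),
        "true_front_axis_deg": truth.true_front_axis.tolist(),
        "true_back_front_ratio": truth.true_back_front_ratio.tolist(),
        "true_protrusions": truth.true_protrusions,
    }
    Path(json_path).write_text(json.dumps(payload, indent=1))
    if masks_tiff is not None:
        write_mask_tiff(masks_tiff, truth.true_masks)
    if activation_tiff is not None:
        tifffile.imwrite(activation_tiff,
                         truth.true_activation_field.astype(np.float32),
                         photometric='minisblack')


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ----------------------------------------------------------------- tables

def write_polarity_records(path: str | Path,
                           records: list[PolarityRecord]) -> None:
    cols = ["cell_id", "frame", "time", "back_index", "front_index",
            "back_front_ratio", "total_index", "reason"]
    df = pd.DataFrame([vars(r) for r in records], columns=cols)
    df = df.rename(columns={"time": "t_min"})
    df.to_csv(path, index=False)


def read_polarity_records(path: str | Path) -> list[PolarityRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        reason = row["reason"]
        out.append(PolarityRecord(
            cell_id=str(row["cell_id"]), frame=int(row["frame"]),
            time=float(row["t_min"]), back_index=row["back_index"],
            front_index=row["front_index"],
            back_front_ratio=row["back_front_ratio"],
            total_index=row["total_index"],
            reason=None if pd.isna(reason) else str(reason),
        ))
    return out


def write_protrusions(path: str | Path, protrusions: list[Protrusion]) -> None:
    rows = [{
        "cell_id": p.cell_id, "frame": p.frame,
        "base_x_um": p.base[0], "base_y_um": p.base[1],
        "tip_x_um": p.tip[0], "tip_y_um": p.tip[1],
        "length_um": p.length, "direction_deg": p.direction,
    } for p in protrusions]
    cols = ["cell_id", "frame", "base_x_um", "base_y_um", "tip_x_um",
            "tip_y_um", "length_um", "direction_deg"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_polar_histogram(path: str | Path, hist: PolarHistogram) -> None:
    df = pd.DataFrame({
        "bin_start_deg": hist.bin_edges[:-1],
        "bin_end_deg": hist.bin_edges[1:],
        "count": hist.counts,
        "frequency": hist.frequencies,
    })
    df.to_csv(path, index=False)


def write_heatmap_csv(path: str | Path, heatmap: HeatmapMatrix) -> None:
    frame = heatmap.to_frame()
    frame.index.name = "cell_id"
    frame.to_csv(path)


def write_profile(path: str | Path, profile: LineScanProfile) -> None:
    pd.DataFrame({
        "arclength_um": profile.arclength,
        "normalized_position": profile.normalized_position,
        "intensity": profile.intensity,
    }).to_csv(path, index=False)


def write_motility_summaries(path: str | Path,
                             summaries: list[MotilitySummary]) -> None:
    pd.DataFrame([vars(s) for s in summaries]).to_csv(path, index=False)
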