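"""Pipeline orchestration: generate or load data, run the ratio chain,
and write polarity, protrusion and motility outputs plus a run manifest.

Each run writes into a fresh timestamped directory under the configured
output directory, so reruns never mutate prior outputs.  The manifest
echoes the config and records a SHA-256 hash of every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import __version__, io, plots
from .config import PipelineConfig
from .motility import Trajectory, summarize_track
from .polarity import (PolarityAxis, PolarityRecord, back_front_indices,
                       build_heatmap, derive_axis_from_track, detect_crossing,
                       region_pair_series)
from .protrusions import (build_polar_histogram, detect_protrusions,
                          protrusion_angle_samples)
from .ratio import CellMask, RatioImage, process_frame
from .synthetic import (generate_polarized_cell_movie,
                        trajectory_from_ground_truth)

log = logging.getLogger(__name__)

ALL_STAGES = ("ratio", "polarity", "protrusions", "motility")


@dataclass
class RunManifest:
    config: dict
    version: str
    run_dir: str
    stages: list[str]
    file_hashes: dict[str, str] = field(default_factory=dict)
    warnings: int = 0
    extras: dict = field(default_factory=dict)


class _WarningCounter(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.count = 0

    def emit(self, record: logging.LogRecord) -> None:
        self.count += 1


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_dict(config: PipelineConfig) -> dict:
    def unwrap(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {f.name: unwrap(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)}
        if isinstance(obj, (tuple, list)):
            return [unwrap(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj
    return unwrap(config)


def _box_region(box: list[int], shape: tuple[int, int]) -> np.ndarray:
    region = np.zeros(shape, dtype=bool)
    r0, r1, c0, c1 = box
    region[r0:r1, c0:c1] = True
    return region


def _half_plane_regions(truth, shape: tuple[int, int], pixel_size: float):
    """Lab-frame front (A) and back (B) half-planes of the first frame,
    used to follow a repolarizing cell the way a fixed A/B annotation
    would."""
    from .polarity import raster_to_um

    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    x, y = raster_to_um(rows, cols, shape, pixel_size)
    cx, cy = truth.true_centroid_track[0]
    theta = np.radians(truth.true_front_axis[0])
    proj = (x - cx) * np.cos(theta) + (y - cy) * np.sin(theta)
    return proj >= 0, proj < 0   # A = initial front, B = initial back


def run_pipeline(config: PipelineConfig, run_name: str | None = None,
                 stages: tuple[str, ...] = ALL_STAGES) -> RunManifest:
    """Execute the configured stages and write all outputs.

    Stage order: (optional) synthesis -> background subtraction -> masking
    -> windowed ratio -> low-tail exclusion -> normalize/smooth -> polarity
    records -> protrusions and angles -> motility summaries.
    """
    if run_name is None:
        run_name = datetime.now(timezone.utc).strftime("run-%Y%m%dT%H%M%S.%f")
    out = Path(config.output_dir) / run_name
    out.mkdir(parents=True, exist_ok=False)

    counter = _WarningCounter()
    logging.getLogger("fretpolar").addHandler(counter)
    logging.getLogger("fretpolar").setLevel(config.log_level)
    truth = None
    try:
        # ---- inputs: synthesize or load -------------------------------
        if config.synthetic is not None:
            params = dataclasses.replace(config.synthetic,
                                         rng_seed=config.rng_seed)
            movie, truth = generate_polarized_cell_movie(params)
            tracks = [trajectory_from_ground_truth(truth)]
            io.write_movie_tiff(out / "movie.tif", movie)
            io.write_ground_truth(out / "ground_truth.json", truth,
                                  masks_tiff=out / "true_masks.tif")
            io.write_trajectories(out / "trajectories.csv", tracks)
        else:
            movie = io.read_movie_tiff(config.input.movie_tiff)
            tracks = (io.read_trajectories(config.input.trajectories_csv)
                      if config.input.trajectories_csv else [])

        track = tracks[0] if tracks else None
        results = _run_stages(config, movie, track, truth, out, stages)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed in {out}: {exc}") from exc
    finally:
        logging.getLogger("fretpolar").removeHandler(counter)

    manifest = RunManifest(
        config=_config_dict(config), version=__version__,
        run_dir=str(out), stages=list(stages), warnings=counter.count,
        extras=results,
    )
    for f in sorted(out.iterdir()):
        if f.name != "manifest.json":
            manifest.file_hashes[f.name] = _sha256(f)
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1, default=str))
    return manifest


def _run_stages(config, movie, track, truth, out: Path,
                stages) -> dict:
    extras: dict = {}
    ratios: list[RatioImage] = []
    masks: list[CellMask] = []
    need_ratio = bool({"ratio", "polarity"} & set(stages)) or \
        "protrusions" in stages

    if need_ratio:
        qc_rows = []
        for t in range(movie.n_frames):
            try:
                cells = process_frame(movie.donor_frames[t],
                                      movie.fret_frames[t], config.ratio)
            except ValueError as exc:
                raise RuntimeError(f"ratio stage, frame {t}: {exc}") from exc
            if not cells:
                raise RuntimeError(f"ratio stage, frame {t}: no cell found")
            # single-cell pipeline: keep the largest detected cell
            cell, ratio, qc = max(cells, key=lambda cr: cr[0].area)
            cell.frame = t
            ratios.append(ratio)
            masks.append(cell)
            qc_rows.append({"frame": t, **qc})
        import pandas as pd
        pd.DataFrame(qc_rows).to_csv(out / "qc.csv", index=False)
        io.write_ratio_tiff(out / "ratio.tif", ratios)
        io.write_mask_tiff(out / "masks.tif",
                           np.stack([m.mask for m in masks]))
        plots.save_ratio_preview(out / "ratio_preview.png", ratios[0])

    if "polarity" in stages:
        records = _polarity_stage(config, movie, track, ratios, masks)
        io.write_polarity_records(out / "polarity.csv", records)
        good = [r for r in records if r.defined]
        if good:
            heatmap = build_heatmap({"cell0": good},
                                    quantity="back_front_ratio")
            io.write_heatmap_csv(out / "heatmap_back_front.csv", heatmap)
            plots.plot_heatmap(out / "heatmap_back_front.png", heatmap)
        regions = _select_regions(config, truth, movie)
        if regions is not None:
            series = region_pair_series(ratios, regions[0], regions[1],
                                        times=movie.frame_times)
            series.to_csv(out / "region_pair.csv", index=False)
            crossing = detect_crossing(series)
            extras["region_pair_crossing_frame"] = crossing

    if "protrusions" in stages:
        per_frame = {}
        all_prots = []
        for t, mask in enumerate(masks):
            prots = detect_protrusions(
                mask, movie.pixel_size,
                body_opening_radius=config.protrusion.body_opening_radius,
                min_length=config.protrusion.min_length,
                cell_id="cell0", frame=t)
            per_frame[t] = prots
            all_prots.extend(prots)
        io.write_protrusions(out / "protrusions.csv", all_prots)
        if track is not None:
            samples = protrusion_angle_samples(
                per_frame, track, lookahead=config.protrusion.lookahead)
            hist = build_polar_histogram(
                samples, bin_width=config.protrusion.bin_width)
            io.write_polar_histogram(out / "protrusion_angles.csv", hist)
            plots.plot_polar_histogram(out / "protrusion_angles.png", hist)
            extras["n_protrusion_samples"] = len(samples)

    if "motility" in stages and track is not None:
        summary = summarize_track(track)
        io.write_motility_summaries(out / "motility.csv", [summary])
        plots.plot_tracks(out / "tracks.png", [track])
        extras["persistence"] = summary.persistence

    return extras


def _polarity_stage(config, movie, track, ratios, masks) -> list[PolarityRecord]:
    records = []
    lookahead = config.polarity.lookahead
    last_axis: PolarityAxis | None = None
    for t in range(movie.n_frames):
        axis = None
        if config.polarity.axis_source == "annotated":
            centroid = _mask_centroid_um(masks[t], movie.pixel_size)
            axis = PolarityAxis(centroid,
                                config.polarity.annotated_direction,
                                source="annotated")
        elif track is not None:
            try:
                axis = derive_axis_from_track(track, t, lookahead)
            except ValueError:
                # tail frames (or a stalled cell): reuse the last known axis
                if last_axis is not None:
                    axis = PolarityAxis(track.positions[min(t, track.n_points - 1)],
                                        last_axis.front_direction,
                                        source=last_axis.source)
        if axis is None:
            records.append(PolarityRecord("cell0", t,
                                          float(movie.frame_times[t]),
                                          reason="no_axis"))
            continue
        last_axis = axis
        records.append(back_front_indices(
            ratios[t], masks[t], axis, movie.pixel_size,
            cell_id="cell0", frame=t, time=float(movie.frame_times[t])))
    return records


def _mask_centroid_um(mask: CellMask, pixel_size: float) -> np.ndarray:
    from .polarity import raster_to_um

    rows, cols = np.nonzero(mask.mask)
    x, y = raster_to_um(rows, cols, mask.mask.shape, pixel_size)
    return np.array([x.mean(), y.mean()])


def _select_regions(config, truth, movie):
    shape = movie.frame_shape
    if config.polarity.region_a is not None and \
            config.polarity.region_b is not None:
        return (_box_region(config.polarity.region_a, shape),
                _box_region(config.polarity.region_b, shape))
    if truth is not None and truth.params.get("repolarization_frame") is not None:
        return _half_plane_regions(truth, shape, movie.pixel_size)
    return None
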