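"""Membrane protrusion detection and protrusion-angle statistics.

A protrusion is an actin extension reaching strictly more than 4.5 µm
beyond the cell body.  The cell body is recovered by morphological opening
of the mask with a disc; candidate protrusions are the connected
components of mask-minus-body that touch the body, and their length is the
largest distance from a component pixel to the body boundary.  The angle
between each protrusion and the subsequent migration direction is folded
to [0, 180] degrees and summarized as a polar histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as _label
from skimage.morphology import disk, opening

from .motility import Trajectory
from .polarity import derive_axis_from_track, raster_to_um
from .ratio import CellMask

log = logging.getLogger(__name__)

__all__ = [
    "Protrusion",
    "ProtrusionAngleSample",
    "PolarHistogram",
    "detect_protrusions",
    "angle_between_directions",
    "protrusion_angle_samples",
    "build_polar_histogram",
]

MIN_PROTRUSION_UM = 4.5


@dataclass
class Protrusion:
    """One retained membrane extension."""

    cell_id: str
    frame: int
    base: np.ndarray     # µm, on the cell-body boundary
    tip: np.ndarray      # µm
    length: float        # µm beyond the body boundary
    direction: float     # degrees in [0, 360), base -> tip

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.tip = np.asarray(self.tip, dtype=float)
        self.direction = float(self.direction) % 360.0


@dataclass
class ProtrusionAngleSample:
    protrusion_direction: float   # degrees
    migration_direction: float    # degrees
    angle_between: float          # degrees in [0, 180]


@dataclass
class PolarHistogram:
    """Histogram of protrusion-migration angles over [0, 180] degrees."""

    bin_edges: np.ndarray
    counts: np.ndarray
    total: int
    normalized: bool = False

    @property
    def frequencies(self) -> np.ndarray:
        if self.total == 0:
            return np.zeros_like(self.counts, dtype=float)
        return self.counts / self.total


def detect_protrusions(
    mask: CellMask | np.ndarray,
    pixel_size: float,
    body_opening_radius: float = 3.0,
    min_length: float = MIN_PROTRUSION_UM,
    cell_id: str = "cell",
    frame: int = 0,
) -> list[Protrusion]:
    """Detect extensions longer than ``min_length`` µm beyond the cell body.

    The body is the morphological opening of the mask with a disc of
    ``body_opening_radius`` µm.  A candidate is a connected component of
    the mask outside the body that touches the body; its length is the
    maximum distance from its pixels to the body, minus one pixel to
    correct the pixel-centre overestimate of the distance to the boundary.
    Retention is strict: length must exceed ``min_length``.
    """
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask).astype(bool)
    radius_px = max(1, int(round(body_opening_radius / pixel_size)))
    # decomposed footprint: a large disc opening is otherwise prohibitively
    # slow and memory-hungry
    body = opening(m, disk(radius_px, decomposition="sequence")).astype(bool)
    if not body.any():
        raise ValueError(
            f"opening with radius {body_opening_radius} µm erased the mask; "
            "use a smaller body_opening_radius")
    # distance (pixels) to the nearest body pixel, with that pixel's indices
    dist, (inds_r, inds_c) = ndi.distance_transform_edt(
        ~body, return_indices=True)
    candidates = m & ~body
    labels, n = _label(candidates, return_num=True, connectivity=2)
    body_dilated = ndi.binary_dilation(body, structure=np.ones((3, 3)))
    out: list[Protrusion] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if not (comp & body_dilated).any():
            continue  # detached debris, not an extension of the body
        comp_dist = np.where(comp, dist, -np.inf)
        tip_r, tip_c = np.unravel_index(np.argmax(comp_dist), comp.shape)
        # one-pixel boundary correction: EDT measures to the nearest body
        # pixel centre, which overshoots the body boundary
        length_um = (dist[tip_r, tip_c] - 1.0) * pixel_size
        if not length_um > min_length:
            continue
        base_r, base_c = inds_r[tip_r, tip_c], inds_c[tip_r, tip_c]
        tx, ty = raster_to_um(np.array([tip_r]), np.array([tip_c]),
                              m.shape, pixel_size)
        bx, by = raster_to_um(np.array([base_r]), np.array([base_c]),
                              m.shape, pixel_size)
        direction = np.degrees(np.arctan2(ty[0] - by[0], tx[0] - bx[0]))
        out.append(Protrusion(
            cell_id=cell_id, frame=frame,
            base=np.array([bx[0], by[0]]), tip=np.array([tx[0], ty[0]]),
            length=float(length_um), direction=float(direction) % 360.0,
        ))
    return out


def angle_between_directions(a: float, b: float) -> float:
    """Smallest unsigned angle between two directions, in [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def protrusion_angle_samples(
    protrusions_per_frame: dict[int, list[Protrusion]],
    track: Trajectory,
    lookahead: int = 1,
) -> list[ProtrusionAngleSample]:
    """Angle between each protrusion and the subsequent migration direction.

    The migration direction at a frame is the direction of the track's net
    displacement over the next ``lookahead`` frames.  Frames with zero
    displacement are skipped with a logged count.
    """
    samples: list[ProtrusionAngleSample] = []
    skipped = 0
    for frame, prots in sorted(protrusions_per_frame.items()):
        if not prots:
            continue
        try:
            axis = derive_axis_from_track(track, frame, lookahead)
        except ValueError:
            skipped += 1
            continue
        for prot in prots:
            samples.append(ProtrusionAngleSample(
                protrusion_direction=prot.direction,
                migration_direction=axis.front_direction,
                angle_between=angle_between_directions(
                    prot.direction, axis.front_direction),
            ))
    if skipped:
        log.info("skipped %d frames with zero or unavailable displacement",
                 skipped)
    return samples


def build_polar_histogram(
    samples: list[ProtrusionAngleSample] | np.ndarray,
    bin_width: float = 20.0,
    normalized: bool = False,
) -> PolarHistogram:
    """Histogram of folded angles over [0, 180] degrees.

    Bins are right-open except the last, which is closed at 180 (matching
    ``numpy.histogram``).  ``bin_width`` must divide 180.
    """
    n_bins = 180.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 180")
    edges = np.linspace(0.0, 180.0, int(round(n_bins)) + 1)
    if isinstance(samples, np.ndarray) or (samples and not isinstance(
            samples[0], ProtrusionAngleSample)):
        angles = np.asarray(samples, dtype=float)
    else:
        angles = np.array([s.angle_between for s in samples], dtype=float)
    counts, _ = np.histogram(angles, bins=edges)
    return PolarHistogram(bin_edges=edges, counts=counts,
                          total=int(counts.sum()), normalized=normalized)
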