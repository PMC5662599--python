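"""Ratiometric FRET image processing.

Implements the quantification chain for a single-chain RHOA biosensor:
local background subtraction, cell-mask computation from the summed
donor+FRET image, a windowed FRET/donor ratio with a x1000 scale factor,
exclusion of the dimmest pixels, and min-normalization with mask-aware
Gaussian smoothing.  Because donor and acceptor sit on one polypeptide they
are equimolar in every pixel, so no bleed-through correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu, threshold_triangle
from skimage.measure import label as _label

log = logging.getLogger(__name__)

__all__ = [
    "TwoChannelMovie",
    "RatioConfig",
    "CellMask",
    "RatioImage",
    "subtract_background",
    "compute_cell_mask",
    "compute_ratio_image",
    "exclude_low_tail",
    "normalize_and_smooth",
]


@dataclass
class TwoChannelMovie:
    """Paired donor (CFP) and FRET acquisitions with calibration metadata.

    Parameters
    ----------
    donor_frames, fret_frames : ndarray, shape (n_frames, H, W)
        Intensities in camera counts.
    pixel_size : float
        Microns per pixel.
    frame_interval : float
        Minutes between frames.
    frame_times : ndarray, shape (n_frames,), optional
        Acquisition times in minutes; defaults to ``arange(n) * interval``.
    """

    donor_frames: np.ndarray
    fret_frames: np.ndarray
    pixel_size: float
    frame_interval: float
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.donor_frames = np.asarray(self.donor_frames, dtype=float)
        self.fret_frames = np.asarray(self.fret_frames, dtype=float)
        if self.donor_frames.shape != self.fret_frames.shape:
            raise ValueError("donor and FRET stacks must have identical shapes")
        if self.donor_frames.ndim != 3:
            raise ValueError("frame stacks must be 3-D (frame, row, col)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_times is None:
            self.frame_times = np.arange(self.n_frames) * float(self.frame_interval)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.donor_frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.donor_frames.shape[1:]


@dataclass
class RatioConfig:
    """Tunable parameters of the ratio chain.

    ``scale_factor`` multiplies every ratio (default 1000);
    ``exclusion_percentile`` removes the dimmest pixels of the summed-channel
    histogram (default 5%); ``gaussian_width`` is the filter width in pixels,
    interpreted as 2*sigma (default 2, i.e. sigma = 1 px); ``window_size`` is
    the odd side of the square window the channel sums are taken over.
    """

    scale_factor: float = 1000.0
    exclusion_percentile: float = 5.0
    gaussian_width: float = 2.0
    window_size: int = 3
    min_object_area: int = 50
    mask_threshold_method: str = "otsu"

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if not (0 <= self.exclusion_percentile < 100):
            raise ValueError("exclusion_percentile must be in [0, 100)")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be odd and >= 1")
        if self.gaussian_width < 0:
            raise ValueError("gaussian_width must be >= 0")
        if self.mask_threshold_method not in ("otsu", "triangle"):
            raise ValueError("mask_threshold_method must be 'otsu' or 'triangle'")


@dataclass
class CellMask:
    """Binary mask of one cell in one frame."""

    mask: np.ndarray
    cell_id: int = 0
    frame: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class RatioImage:
    """Per-pixel scaled FRET/donor ratio, defined only inside a mask.

    ``values`` is NaN outside ``defined_mask``.  After normalization the
    minimum defined value is exactly 1.0.
    """

    values: np.ndarray
    defined_mask: np.ndarray
    scale_factor: float = 1000.0
    normalized: bool = False

    def __post_init__(self) -> None:
        self.defined_mask = np.asarray(self.defined_mask).astype(bool)
        self.values = np.asarray(self.values, dtype=float)

    @property
    def defined_values(self) -> np.ndarray:
        return self.values[self.defined_mask]


def subtract_background(
    frame: np.ndarray, background_region: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Subtract the local background level from one channel frame.

    The background estimate is the median of the background-region pixels.
    When no region is supplied, background pixels are auto-selected as those
    below a triangle threshold of the full-frame histogram (pixels without
    significant cell signal).  The corrected frame is clipped at zero.
    """
    frame = np.asarray(frame, dtype=float)
    if background_region is not None:
        region = np.asarray(background_region).astype(bool)
        if region.shape != frame.shape:
            raise ValueError("background_region shape must match frame")
        if not region.any():
            raise ValueError("background_region is empty; supply a nonempty region")
    else:
        thresh = threshold_triangle(frame)
        region = frame < thresh
        if not region.any():
            raise ValueError(
                "automatic background selection found no pixels below the "
                "triangle threshold; pass an explicit background_region"
            )
    estimate = float(np.median(frame[region]))
    corrected = np.clip(frame - estimate, 0.0, None)
    return corrected, estimate


def compute_cell_mask(
    donor: np.ndarray, fret: np.ndarray, config: RatioConfig | None = None
) -> list[CellMask]:
    """Segment cells from the summed background-subtracted channels.

    The donor+FRET sum is thresholded (Otsu by default), connected
    components smaller than ``min_object_area`` are dropped, and each
    surviving component becomes one :class:`CellMask`.  Returns an empty
    list (with a logged warning) when nothing survives.
    """
    config = config or RatioConfig()
    donor = np.asarray(donor, dtype=float)
    fret = np.asarray(fret, dtype=float)
    if donor.shape != fret.shape:
        raise ValueError("donor and fret must have the same shape")
    summed = donor + fret
    if summed.max() <= 0:
        log.warning("summed image is empty; no cell masks found")
        return []
    threshold_fn = {"otsu": threshold_otsu, "triangle": threshold_triangle}[
        config.mask_threshold_method
    ]
    binary = summed > threshold_fn(summed)
    labels, n = _label(binary, return_num=True, connectivity=2)
    masks: list[CellMask] = []
    cell_id = 0
    for lab in range(1, n + 1):
        component = labels == lab
        if component.sum() < config.min_object_area:
            continue
        masks.append(CellMask(mask=component, cell_id=cell_id))
        cell_id += 1
    if not masks:
        log.warning("no connected component reached min_object_area=%d",
                    config.min_object_area)
    return masks


def _window_sum(arr: np.ndarray, window_size: int) -> np.ndarray:
    """Sum over a centred square window, zero-padded at the borders.

    Accumulates shifted copies in (dr, dc) raster order so the per-pixel
    addition sequence matches a naive double loop bit for bit.
    """
    if window_size == 1:
        return arr.copy()
    h = window_size // 2
    H, W = arr.shape
    padded = np.pad(arr, h)
    out = np.zeros_like(arr)
    for dr in range(window_size):
        for dc in range(window_size):
            out = out + padded[dr : dr + H, dc : dc + W]
    return out


def compute_ratio_image(
    donor: np.ndarray,
    fret: np.ndarray,
    mask: CellMask | np.ndarray,
    config: RatioConfig | None = None,
) -> RatioImage:
    """Windowed FRET/donor ratio on a cell mask, times the scale factor.

    Each ratio value is the sum of FRET intensities divided by the sum of
    donor intensities over a ``window_size`` square window intersected with
    the mask.  Pixels whose window carries zero donor signal are undefined.
    """
    config = config or RatioConfig()
    donor = np.asarray(donor, dtype=float)
    fret = np.asarray(fret, dtype=float)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask).astype(bool)
    if donor.shape != fret.shape or donor.shape != m.shape:
        raise ValueError("donor, fret and mask shapes must agree")
    mf = m.astype(float)
    sum_fret = _window_sum(fret * mf, config.window_size)
    sum_donor = _window_sum(donor * mf, config.window_size)
    defined = m & (sum_donor > 0)
    if not defined.any():
        raise ValueError("donor window sums are zero everywhere on the mask")
    values = np.full(donor.shape, np.nan)
    values[defined] = sum_fret[defined] / sum_donor[defined] * config.scale_factor
    return RatioImage(values=values, defined_mask=defined,
                      scale_factor=config.scale_factor)


def exclude_low_tail(
    ratio: RatioImage,
    donor_plus_fret: np.ndarray,
    config: RatioConfig | None = None,
) -> RatioImage:
    """Drop the dimmest defined pixels from the ratio image.

    Removes the ``floor(q * N / 100)`` defined pixels with the lowest
    summed-channel intensity (q = ``exclusion_percentile``).  Intensity ties
    at the cut are broken by (row, column) raster order.
    """
    config = config or RatioConfig()
    intensity = np.asarray(donor_plus_fret, dtype=float)
    if intensity.shape != ratio.values.shape:
        raise ValueError("donor_plus_fret shape must match the ratio image")
    rows, cols = np.nonzero(ratio.defined_mask)
    n = rows.size
    if n == 0:
        raise ValueError("ratio image has no defined pixels")
    k = int(np.floor(config.exclusion_percentile * n / 100.0))
    if k == 0:
        return replace(ratio, values=ratio.values.copy(),
                       defined_mask=ratio.defined_mask.copy())
    if k >= n:
        raise ValueError("low-tail exclusion would remove every defined pixel")
    order = np.lexsort((cols, rows, intensity[rows, cols]))
    drop = order[:k]
    new_mask = ratio.defined_mask.copy()
    new_mask[rows[drop], cols[drop]] = False
    new_values = ratio.values.copy()
    new_values[~new_mask] = np.nan
    return replace(ratio, values=new_values, defined_mask=new_mask)


def masked_gaussian(
    values: np.ndarray, mask: np.ndarray, sigma: float
) -> np.ndarray:
    """Gaussian smoothing by normalized convolution.

    Undefined pixels carry zero weight, so signal never leaks across the
    mask boundary; output is defined on the same mask.
    """
    filled = np.where(mask, values, 0.0)
    num = ndi.gaussian_filter(filled, sigma, mode="constant")
    den = ndi.gaussian_filter(mask.astype(float), sigma, mode="constant")
    out = np.full(values.shape, np.nan)
    out[mask] = num[mask] / den[mask]
    return out


def normalize_and_smooth(
    ratio: RatioImage,
    config: RatioConfig | None = None,
    normalize: bool = True,
) -> RatioImage:
    """Smooth with a mask-aware Gaussian, then normalize the minimum to 1.0.

    The filter width ``gaussian_width`` is read as 2*sigma pixels; width 0
    skips smoothing.  Normalization divides by the post-smoothing defined
    minimum so the lowest defined value lands at exactly 1.0.
    """
    config = config or RatioConfig()
    if not ratio.defined_mask.any():
        raise ValueError("ratio image has no defined pixels")
    sigma = config.gaussian_width / 2.0
    if sigma > 0:
        values = masked_gaussian(ratio.values, ratio.defined_mask, sigma)
    else:
        values = ratio.values.copy()
    normalized = ratio.normalized
    if normalize:
        vmin = np.nanmin(values[ratio.defined_mask])
        if vmin <= 0:
            raise ValueError("cannot normalize: non-positive minimum ratio")
        values = np.where(ratio.defined_mask, values / vmin, np.nan)
        normalized = True
    return replace(ratio, values=values, defined_mask=ratio.defined_mask.copy(),
                   normalized=normalized)


def process_frame(
    donor: np.ndarray,
    fret: np.ndarray,
    config: RatioConfig | None = None,
    background_region: np.ndarray | None = None,
) -> list[tuple[CellMask, RatioImage, dict]]:
    """Run the full per-frame chain: background, mask, ratio, exclusion,
    normalization/smoothing.

    Returns one ``(mask, ratio_image, qc)`` triple per detected cell, where
    ``qc`` carries the background estimates and defined-pixel counts.
    """
    config = config or RatioConfig()
    donor_c, bg_d = subtract_background(donor, background_region)
    fret_c, bg_f = subtract_background(fret, background_region)
    results = []
    for cell in compute_cell_mask(donor_c, fret_c, config):
        ratio = compute_ratio_image(donor_c, fret_c, cell, config)
        ratio = exclude_low_tail(ratio, donor_c + fret_c, config)
        ratio = normalize_and_smooth(ratio, config)
        qc = {
            "background_donor": bg_d,
            "background_fret": bg_f,
            "defined_pixels": int(ratio.defined_mask.sum()),
            "ratio_min": float(np.nanmin(ratio.defined_values)),
            "ratio_max": float(np.nanmax(ratio.defined_values)),
        }
        results.append((cell, ratio, qc))
    return results
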